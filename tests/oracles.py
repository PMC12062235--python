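"""Independent brute-force oracles used to validate the package's numerics.

Every oracle here is written directly from the published definition of the
statistic — literal double loops, enumeration, or generic convex
optimisation — deliberately sharing no code with the package's vectorised
implementations.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def relief_f_oracle(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Literal full-pass Relief-F: double loop over targets and neighbours.

    X is samples × features.  Feature diffs are |x − x'| / range; neighbour
    distance is the sum of diffs (Manhattan on range-scaled values);
    distance ties break by sample index; the miss term carries the
    multi-class prior weight P(class)/ (1 − P(target class)).
    """
    n, p = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = hi - lo
    rng = np.where(rng > 0, rng, 1.0)

    def diff(f, i, j):
        return abs(X[i, f] - X[j, f]) / rng[f]

    classes = sorted(set(y.tolist()))
    prior = {c: float(np.mean(y == c)) for c in classes}
    W = np.zeros(p)
    for i in range(n):
        d = []
        for j in range(n):
            if j == i:
                continue
            d.append((sum(diff(f, i, j) for f in range(p)), j))
        d.sort(key=lambda t: (t[0], t[1]))
        hits = [j for _, j in d if y[j] == y[i]][:k]
        for f in range(p):
            for h in hits:
                W[f] -= diff(f, i, h) / (n * k)
        for c in classes:
            if c == y[i]:
                continue
            misses = [j for _, j in d if y[j] == c][:k]
            w = prior[c] / (1.0 - prior[y[i]])
            for f in range(p):
                for m in misses:
                    W[f] += w * diff(f, i, m) / (n * k)
    return W


def svm_primal_oracle(
    X: np.ndarray, y01: np.ndarray, c: float
) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVM by generic constrained optimisation.

    Solves the primal QP min ½‖w‖² + C Σξ subject to
    y_i(w·x_i + b) ≥ 1 − ξ_i, ξ ≥ 0 with y ∈ {−1, +1}, via trust-constr
    with analytic gradient; returns (w, b).
    """
    n, p = X.shape
    y = 2.0 * y01 - 1.0

    def objective(z):
        w, xi = z[:p], z[p + 1 :]
        return 0.5 * float(w @ w) + c * float(xi.sum())

    def grad(z):
        g = np.zeros_like(z)
        g[:p] = z[:p]
        g[p + 1 :] = c
        return g

    A = np.zeros((n, p + 1 + n))
    A[:, :p] = y[:, None] * X
    A[:, p] = y
    A[np.arange(n), p + 1 + np.arange(n)] = 1.0
    margin = optimize.LinearConstraint(A, lb=1.0, ub=np.inf)
    bounds = optimize.Bounds(
        lb=np.concatenate([np.full(p + 1, -np.inf), np.zeros(n)]),
        ub=np.full(p + 1 + n, np.inf),
    )
    z0 = np.zeros(p + 1 + n)
    z0[p + 1 :] = 1.0  # feasible start: w = 0, b = 0, all slacks 1
    res = optimize.minimize(
        objective,
        z0,
        jac=grad,
        method="trust-constr",
        constraints=[margin],
        bounds=bounds,
        options={"maxiter": 5000, "gtol": 1e-10, "xtol": 1e-12},
    )
    assert res.success, res.message
    return res.x[:p], float(res.x[p])


def svm_cv_oracle(
    X: np.ndarray,
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    c: float,
) -> float:
    """Per-fold refit of the soft-margin SVM via the convex-solver oracle.

    Standardizes each feature on the training fold (sd 0 → scale 1),
    applies the fitted scaling to the held-out fold, classifies by the
    sign of the decision function, and returns the mean fold accuracy.
    """
    accs = []
    for train, test in splits:
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X - mu) / sd
        w, b = svm_primal_oracle(Z[train], y[train], c)
        pred = (Z[test] @ w + b > 0).astype(int)
        accs.append(float(np.mean(pred == y[test])))
    return float(np.mean(accs))


def kendall_tau_b_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Tau-b by enumerating all C(n,2) pairs with the tie correction."""
    n = len(a)
    concordant = discordant = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                ties_a += 1
                ties_b += 1
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - ties_a) * (n0 - ties_b))
    return (concordant - discordant) / denom


def welch_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's t and two-sided p from the textbook formulas."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up by literal enumeration."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        candidate = pvals[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, candidate)
        adj[idx] = min(running_min, 1.0)
    return adj


def cv_sum_oracle(
    pairs: list[tuple[str, str]],
    scores: np.ndarray,
    genes: list[str],
    threshold: float,
) -> dict[str, float]:
    """Aggregated gene scores by literal double loop over (pair, dataset)."""
    acc = {g: 0.0 for g in genes}
    n_pairs, n_ds = scores.shape
    for p in range(n_pairs):
        a, b = pairs[p]
        for d in range(n_ds):
            if scores[p, d] > threshold:
                acc[a] += scores[p, d]
                acc[b] += scores[p, d]
    return acc


def exceedance_p_oracle(null_scores: np.ndarray, observed: float) -> tuple[int, float]:
    """Empirical p by literal recount of exceedances (count / N)."""
    count = 0
    for v in null_scores:
        if v >= observed:
            count += 1
    n = len(null_scores)
    return count, (count if count > 0 else 1) / n
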