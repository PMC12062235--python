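"""Univariate differential-expression baseline.

A deliberately minimal per-gene screen — Welch's t-test with
Benjamini–Hochberg FDR control and a log2 fold-change cutoff — used to
contrast the bivariate ranking against the field's default analysis: genes
whose signal is synergistic (joint, not marginal) are invisible here.

Fold changes are computed on the log2 scale: RNA-Seq values are
log2(x+1)-transformed first, microarray intensities are treated as already
log-scale.  This is a t-test on continuous expression, not a count model;
it is the appropriate baseline for the continuous synthetic cohorts this
package generates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import CASE, CONTROL, ExpressionDataset


def de_analysis(
    dataset: ExpressionDataset,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test with BH adjustment and a |log2FC| cutoff.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``p``,
    ``p_adj`` and ``flagged`` (|log2FC| ≥ ``fc_threshold`` and BH-adjusted
    p < ``p_threshold``).
    """
    y = dataset.labels.to_numpy()
    n0, n1 = (y == CONTROL).sum(), (y == CASE).sum()
    if n0 < 2 or n1 < 2:
        raise ValueError(
            f"{dataset.name}: Welch's t-test needs >= 2 samples per class "
            f"(got {n0} control / {n1} case)"
        )
    values = dataset.matrix.to_numpy(dtype=float)
    logged = np.log2(values + 1.0) if dataset.platform == "rnaseq" else values
    case = logged[:, y == CASE]
    control = logged[:, y == CONTROL]
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    t_res = stats.ttest_ind(case, control, axis=1, equal_var=False)
    pvals = np.asarray(t_res.pvalue)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # constant genes: no evidence
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    flagged = (np.abs(log2fc) >= fc_threshold) & (p_adj < p_threshold)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": p_adj,
            "flagged": flagged,
        },
        index=dataset.matrix.index,
    )


def overlap_report(de: pd.DataFrame, selected: list[str]) -> dict:
    """Fraction of a selected gene list flagged as differentially expressed.

    Returns the fraction plus the 2×2 contingency of selection status vs
    DE flag over all genes in the DE table.
    """
    if not selected:
        raise ValueError("selected gene list is empty")
    missing = [g for g in selected if g not in de.index]
    if missing:
        raise KeyError(f"selected genes absent from DE table: {missing[:5]}")
    sel = pd.Index(selected)
    flagged = de["flagged"]
    n_sel_flagged = int(flagged.loc[sel].sum())
    contingency = pd.DataFrame(
        {
            "flagged": [n_sel_flagged, int(flagged.sum()) - n_sel_flagged],
            "not_flagged": [
                len(sel) - n_sel_flagged,
                int((~flagged).sum()) - (len(sel) - n_sel_flagged),
            ],
        },
        index=["selected", "not_selected"],
    )
    return {
        "fraction_flagged": n_sel_flagged / len(sel),
        "n_selected": len(sel),
        "n_selected_flagged": n_sel_flagged,
        "contingency": contingency,
    }
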