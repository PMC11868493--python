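"""Differential correlation of gene pairs between patient groups.

Patients are stratified into cytolytically active (GzB-high) and inactive
(GzB-low) groups at the median of per-patient averaged granzyme-B
expression; within each group all pairwise gene correlations (Spearman by
default) are computed with two-tailed p-values, and each pair is classified
by how its association changes between the groups:

* ``conserved-positive`` / ``conserved-negative`` — significant with the
  same sign in both groups;
* ``lost-in-low`` / ``lost-in-high`` — significant in one group only;
* ``sign-flipped`` — significant with opposite signs;
* ``null-in-both`` — otherwise.

Significance is two-tailed at a configurable α (default 0.05) with no
multiple-testing correction by default; a Benjamini–Hochberg option exists.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .survival import median_split

DEFAULT_ALPHA = 0.05


def stratify_by_gzb(per_patient_gzb: pd.Series) -> pd.Series:
    """Median-cutoff labels: value > median -> GzB-high, <= median -> GzB-low."""
    labels = median_split(per_patient_gzb.to_numpy(), labels=("GzB-low", "GzB-high"))
    return pd.Series(labels, index=per_patient_gzb.index, name="group")


class CorrelationMatrices:
    """Pairwise gene correlations (r) and two-tailed p-values for one group."""

    def __init__(self, r: pd.DataFrame, p: pd.DataFrame, method: str, n: int):
        self.r = r
        self.p = p
        self.method = method
        self.n = n

    @property
    def genes(self) -> list[str]:
        return list(self.r.columns)


def group_correlations(
    panel: pd.DataFrame, genes=None, method: str = "spearman"
) -> CorrelationMatrices:
    """All pairwise gene correlations within one patient group.

    ``panel`` is a patient-by-gene DataFrame (non-gene columns like
    patient_id/group are ignored when ``genes`` is None and they are not
    numeric gene columns). A constant gene yields NaN (undefined) for all
    its pairs rather than a number.
    """
    if method not in ("pearson", "spearman"):
        raise InputError(f"method must be 'pearson' or 'spearman', got {method!r}")
    if genes is None:
        genes = [c for c in panel.columns if c not in ("patient_id", "group")]
    data = panel[list(genes)].to_numpy(dtype=float)
    if not np.isfinite(data).all():
        raise InputError("expression values must be finite")
    n = len(data)
    if n < 3:
        raise InputError("group_correlations requires >= 3 patients per group")
    g = len(genes)
    r = np.eye(g)
    p = np.zeros((g, g))
    for i, j in itertools.combinations(range(g), 2):
        x, y = data[:, i], data[:, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rij = pij = float("nan")
        else:
            res = stats.pearsonr(x, y) if method == "pearson" else stats.spearmanr(x, y)
            rij, pij = float(res.statistic), float(res.pvalue)
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
    genes = list(genes)
    return CorrelationMatrices(
        pd.DataFrame(r, index=genes, columns=genes),
        pd.DataFrame(p, index=genes, columns=genes),
        method,
        n,
    )


def _classify(r_h: float, p_h: float, r_l: float, p_l: float, alpha: float) -> str:
    sig_h = np.isfinite(p_h) and p_h < alpha
    sig_l = np.isfinite(p_l) and p_l < alpha
    if sig_h and sig_l:
        if np.sign(r_h) == np.sign(r_l):
            return "conserved-positive" if r_h > 0 else "conserved-negative"
        return "sign-flipped"
    if sig_h:
        return "lost-in-low"
    if sig_l:
        return "lost-in-high"
    return "null-in-both"


def compare_correlations(
    mat_high: CorrelationMatrices,
    mat_low: CorrelationMatrices,
    alpha: float = DEFAULT_ALPHA,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Classify every gene pair by its change in association between groups.

    Returns a tidy DataFrame (gene_a, gene_b, r_high, p_high, r_low, p_low,
    cls), symmetric in gene-pair order. With ``bh_correct`` the p-values are
    Benjamini–Hochberg adjusted across pairs before thresholding (off by
    default).
    """
    if mat_high.genes != mat_low.genes:
        raise InputError("correlation matrices cover different gene panels")
    genes = mat_high.genes
    pairs = list(itertools.combinations(genes, 2))
    p_high = np.array([mat_high.p.loc[a, b] for a, b in pairs])
    p_low = np.array([mat_low.p.loc[a, b] for a, b in pairs])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        for p in (p_high, p_low):
            finite = np.isfinite(p)
            if finite.any():
                p[finite] = multipletests(p[finite], method="fdr_bh")[1]
    rows = []
    for k, (a, b) in enumerate(pairs):
        r_h = float(mat_high.r.loc[a, b])
        r_l = float(mat_low.r.loc[a, b])
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "r_high": r_h,
                "p_high": float(p_high[k]),
                "r_low": r_l,
                "p_low": float(p_low[k]),
                "cls": _classify(r_h, float(p_high[k]), r_l, float(p_low[k]), alpha),
            }
        )
    return pd.DataFrame(rows)
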