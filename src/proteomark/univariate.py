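"""Per-proteoform differential abundance analysis.

For each proteoform the case/control contrast is summarised by the log2 ratio
of group mean abundances, a two-sided Wilcoxon rank-sum (Mann-Whitney)
p-value, and a Benjamini-Hochberg adjusted FDR. A proteoform is *selected*
when its mean fold change exceeds the threshold (default 1.3, i.e. a +/-30%
change) and its FDR is below alpha (default 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError
from .matrix import AbundanceMatrix

#: Largest combined sample size at which the exact (enumerated) rank-sum null
#: is used when the row has no ties; larger samples or tied rows fall back to
#: the normal approximation with tie and continuity corrections.
EXACT_MAX_N = 30


def default_pseudocount(matrix: AbundanceMatrix) -> float:
    """Half the smallest positive abundance in the matrix.

    Keeps fold changes finite for non-detected (zero) proteins without
    dominating genuine signal. Falls back to 0.5 for an all-zero matrix.
    """
    arr = matrix.values.to_numpy()
    positive = arr[arr > 0]
    if positive.size == 0:
        return 0.5
    return float(positive.min()) / 2.0


def log2_fold_change(matrix: AbundanceMatrix, pseudocount: float | None = None) -> pd.Series:
    """log2((mean_case + pc) / (mean_control + pc)) per proteoform.

    With ``pseudocount=0`` a zero group mean yields ``+/-inf`` (or NaN for
    0/0) and a warning is emitted; rows are never dropped.
    """
    if pseudocount is None:
        pseudocount = default_pseudocount(matrix)
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    case_mean = matrix.case_array().mean(axis=1) + pseudocount
    ctrl_mean = matrix.control_array().mean(axis=1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(case_mean) - np.log2(ctrl_mean)
    if not np.isfinite(lfc).all():
        warnings.warn(
            "zero group mean with pseudocount 0 produced non-finite log2 fold changes",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.Series(lfc, index=matrix.values.index, name="log2fc")


def _row_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def wilcoxon_rank_sum(matrix: AbundanceMatrix) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p-value per proteoform.

    Uses the exact null distribution for small tie-free rows (combined
    n <= 30) and the tie-corrected normal approximation with continuity
    correction otherwise. A constant row yields p = 1.
    """
    case = matrix.case_array()
    ctrl = matrix.control_array()
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise InputError("need at least 2 samples per group for the rank-sum test")
    pvals = np.array([_row_pvalue(case[i], ctrl[i]) for i in range(case.shape[0])])
    return pd.Series(pvals, index=matrix.values.index, name="pvalue")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log2_threshold(fc_threshold: float, fc_scale: str) -> float:
    if fc_scale == "ratio":
        if fc_threshold < 1:
            raise ParameterError("fc_threshold must be >= 1 on the ratio scale")
        return math.log2(fc_threshold)
    if fc_scale == "log2":
        if fc_threshold < 0:
            raise ParameterError("fc_threshold must be >= 0 on the log2 scale")
        return fc_threshold
    raise ParameterError(f"fc_scale must be 'ratio' or 'log2', got {fc_scale!r}")


def differential_abundance(
    matrix: AbundanceMatrix,
    fc_threshold: float = 1.3,
    alpha: float = 0.05,
    pseudocount: float | None = None,
    fc_scale: str = "ratio",
) -> pd.DataFrame:
    """Full univariate stage: log2FC, rank-sum p, BH FDR and selection flag.

    Returns a DataFrame indexed by accession with columns ``log2fc``,
    ``pvalue``, ``fdr`` and ``selected``. Selection requires
    ``|log2fc| >= log2(fc_threshold)`` (``fc_scale="ratio"``, the default
    reads the threshold as a mean ratio, so 1.3 means a +/-30% change) and
    ``fdr < alpha`` (strict).
    """
    thr = _log2_threshold(fc_threshold, fc_scale)
    lfc = log2_fold_change(matrix, pseudocount=pseudocount)
    pv = wilcoxon_rank_sum(matrix)
    fdr = bh_adjust(pv.to_numpy())
    table = pd.DataFrame({"log2fc": lfc, "pvalue": pv, "fdr": fdr})
    table["selected"] = (table["log2fc"].abs() >= thr) & (table["fdr"] < alpha)
    return table


@dataclass(frozen=True)
class SelectionSummary:
    """Selected proteoform set with its up/down split by log2FC sign."""

    selected: frozenset
    n_up: int
    n_down: int

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def select_univariate(
    results: pd.DataFrame,
    fc_threshold: float = 1.3,
    alpha: float = 0.05,
    fc_scale: str = "ratio",
) -> SelectionSummary:
    """Apply the joint FC/FDR gate to a univariate results table."""
    thr = _log2_threshold(fc_threshold, fc_scale)
    mask = (results["log2fc"].abs() >= thr) & (results["fdr"] < alpha)
    sel = results.index[mask]
    n_up = int((results.loc[sel, "log2fc"] > 0).sum())
    n_down = int((results.loc[sel, "log2fc"] < 0).sum())
    return SelectionSummary(selected=frozenset(sel), n_up=n_up, n_down=n_down)
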