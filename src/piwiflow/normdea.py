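"""Median-of-ratios normalization and negative-binomial Wald differential
expression.

This is a self-contained two-group NB workflow in the DESeq2 style: size
factors by the median-of-ratios rule, per-feature group means on the
normalized scale, a pooled method-of-moments dispersion, and a Wald test
on the log fold change with Benjamini-Hochberg FDR.  It deliberately omits
dispersion shrinkage, independent filtering and outlier replacement; it is
a transparent surrogate, not a DESeq2 reimplementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from piwiflow.containers import CountMatrix, PiwiflowError

#: pseudocount on the normalized scale used for log2FC stability at low counts
PSEUDOCOUNT = 0.5
#: floor for the method-of-moments dispersion (prevents degenerate Wald SEs)
DISPERSION_FLOOR = 1e-8


class NormalizationError(PiwiflowError):
    pass


class DesignError(PiwiflowError):
    pass


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For sample j the factor is the median over usable features i of
    counts[i, j] / geomean_i, where geomean_i is the geometric mean of
    feature i across samples; usable features are those with geomean > 0
    (i.e. no zero count in any sample).
    """
    mat = _as_frame(counts)
    x = mat.to_numpy(dtype=float)
    usable = (x > 0).all(axis=1)
    if not usable.any():
        raise NormalizationError("no feature with all-positive counts; cannot compute size factors")
    logx = np.log(x[usable])
    log_geomean = logx.mean(axis=1)
    log_ratios = logx - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def normalize(counts: CountMatrix | pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Element-wise division of each sample column by its size factor."""
    mat = _as_frame(counts)
    missing = set(mat.columns) - set(factors.index)
    if missing:
        raise KeyError(f"size factors missing for samples: {sorted(missing)[:5]}")
    return mat.div(factors.reindex(mat.columns), axis=1)


def _pooled_dispersion(y1: np.ndarray, y2: np.ndarray, m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion pooled across the two groups.

    Solves var = mu + alpha * mu^2 per group and pools by residual degrees
    of freedom; floored at DISPERSION_FLOOR.
    """
    n1, n2 = y1.shape[1], y2.shape[1]
    v1 = y1.var(axis=1, ddof=1)
    v2 = y2.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (v1 - m1) / np.square(m1)
        a2 = (v2 - m2) / np.square(m2)
    a1 = np.nan_to_num(a1, nan=0.0, posinf=0.0, neginf=0.0)
    a2 = np.nan_to_num(a2, nan=0.0, posinf=0.0, neginf=0.0)
    alpha = ((n1 - 1) * a1 + (n2 - 1) * a2) / (n1 + n2 - 2)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_wald_test(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series,
    group_labels: pd.Series,
    drop_all_zero: bool = True,
) -> pd.DataFrame:
    """Two-group NB Wald test per feature.

    log2FC is log2((mean2 + pc) / (mean1 + pc)) of normalized-scale group
    means with pseudocount pc = 0.5; the Wald statistic divides the natural
    log fold change by a delta-method SE from the NB variance
    mu + alpha*mu^2 with the pooled method-of-moments dispersion; two-sided
    p from a t reference with n1 + n2 - 2 df; FDR by Benjamini-Hochberg.

    Returns a DataFrame (feature, kind?, baseMean1, baseMean2, log2FC, p, FDR)
    where group 1 / group 2 follow the sorted order of the two label levels
    unless ``group_labels`` is an ordered Categorical.
    """
    mat = _as_frame(counts)
    group_labels = pd.Series(group_labels).reindex(mat.columns)
    if group_labels.isna().any():
        raise DesignError("group labels missing for some samples")
    if isinstance(group_labels.dtype, pd.CategoricalDtype) and group_labels.cat.ordered:
        levels = [l for l in group_labels.cat.categories if l in set(group_labels)]
    else:
        levels = sorted(pd.unique(group_labels))
    if len(levels) != 2:
        raise DesignError(f"exactly two group levels required, got {levels}")
    g1, g2 = levels
    idx1 = group_labels == g1
    idx2 = group_labels == g2
    if idx1.sum() < 2 or idx2.sum() < 2:
        raise DesignError("each group needs at least 2 samples")

    norm = normalize(mat, factors)
    if drop_all_zero:
        nonzero = mat.sum(axis=1) > 0
        norm = norm.loc[nonzero]
    y1 = norm.loc[:, idx1.to_numpy()].to_numpy()
    y2 = norm.loc[:, idx2.to_numpy()].to_numpy()
    m1 = y1.mean(axis=1)
    m2 = y2.mean(axis=1)
    alpha = _pooled_dispersion(y1, y2, m1, m2)

    pc = PSEUDOCOUNT
    lfc_nat = np.log(m2 + pc) - np.log(m1 + pc)
    # delta-method variance of log(mean_g + pc) with NB variance per observation
    var1 = (m1 + alpha * np.square(m1)) / y1.shape[1] / np.square(m1 + pc)
    var2 = (m2 + alpha * np.square(m2)) / y2.shape[1] / np.square(m2 + pc)
    se = np.sqrt(var1 + var2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc_nat / se, 0.0)
    # t reference with pooled residual df: the method-of-moments dispersion
    # makes the SE itself noisy at cohort-scale n, and the t tail absorbs
    # that extra variability (a plain normal reference is anticonservative)
    df = y1.shape[1] + y2.shape[1] - 2
    pvals = 2.0 * stats.t.sf(np.abs(wald), df)
    pvals = np.clip(pvals, 0.0, 1.0)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    out = pd.DataFrame(
        {
            "baseMean1": m1,
            "baseMean2": m2,
            "log2FC": lfc_nat / np.log(2.0),
            "stat": wald,
            "p": pvals,
            "FDR": fdr,
        },
        index=norm.index,
    )
    if isinstance(counts, CountMatrix) and "kind" in counts.annotations.columns:
        out.insert(0, "kind", counts.annotations.loc[out.index, "kind"])
    out.attrs["groups"] = (g1, g2)
    return out


def call_significant(dea: pd.DataFrame, fdr_cutoff: float = 0.05) -> dict[str, list[str]]:
    """Split features with FDR strictly below the cutoff by log2FC sign."""
    if not 0.0 < fdr_cutoff < 1.0:
        raise ValueError(f"fdr_cutoff must lie in (0, 1), got {fdr_cutoff!r}")
    sig = dea[dea["FDR"] < fdr_cutoff]
    return {
        "up": sig.index[sig["log2FC"] > 0].tolist(),
        "down": sig.index[sig["log2FC"] < 0].tolist(),
        "unclassified": sig.index[sig["log2FC"] == 0].tolist(),
    }
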