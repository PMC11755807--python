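"""Total TE / piRNA levels, class composition, the TE:piRNA ratio,
correlation and group-comparison tests, and control-extremum cutoffs.

The TE:piRNA ratio summarizes the coordinated shift the analysis targets:
a low ratio means suppressed transposable elements together with elevated
piRNAs.  Cohorts are stratified with cutoffs derived from the control
group alone (the minimum for TE-like statistics, the maximum for
piRNA-like statistics), so "abnormal" means outside the range observed in
healthy controls; values on the boundary fall on the control-like side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CutoffRule:
    """Control-derived dichotomization of one per-sample statistic."""

    statistic: str
    mode: str  # "control-minimum" or "control-maximum"
    cutoff: float

    def assign(self, values: pd.Series) -> pd.Series:
        """Map values to {'low', 'high'}; boundary values are control-like."""
        v = pd.Series(values, dtype=float)
        if self.mode == "control-minimum":
            return pd.Series(np.where(v < self.cutoff, "low", "high"), index=v.index)
        return pd.Series(np.where(v > self.cutoff, "high", "low"), index=v.index)


def totals(
    te_normalized: pd.DataFrame,
    pirna_normalized: pd.DataFrame,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample total normalized TE and piRNA levels and their ratio.

    The ratio is left NaN (and flagged) where the piRNA total is zero.
    """
    if set(te_normalized.columns) != set(pirna_normalized.columns):
        raise ValueError("TE and piRNA matrices must share the same sample set")
    te_tot = te_normalized.sum(axis=0)
    pi_tot = pirna_normalized.reindex(columns=te_normalized.columns).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pi_tot > 0, te_tot / pi_tot, np.nan)
    out = pd.DataFrame(
        {
            "total_te": te_tot,
            "total_pirna": pi_tot,
            "ratio": ratio,
            "ratio_defined": pi_tot > 0,
        }
    )
    out.index.name = "sample"
    if groups is not None:
        out.insert(0, "group", pd.Series(groups).reindex(out.index))
    return out


def composition(te_normalized: pd.DataFrame, te_class: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    """Per-class fraction of the total TE level per sample, plus the cohort
    mean of the per-sample fractions."""
    te_class = pd.Series(te_class).reindex(te_normalized.index)
    if te_class.isna().any():
        raise ValueError("every TE feature must carry a class annotation")
    by_class = te_normalized.groupby(te_class, observed=True).sum()
    tot = by_class.sum(axis=0)
    frac = by_class.div(tot, axis=1).T  # samples x classes
    return frac, frac.mean(axis=0)


def control_cutoff(values: pd.Series, is_control: pd.Series, mode: str, name: str = "") -> CutoffRule:
    """Cutoff = the control group's minimum (mode='control-minimum') or
    maximum (mode='control-maximum')."""
    values = pd.Series(values, dtype=float)
    is_control = pd.Series(is_control).reindex(values.index).astype(bool)
    ctrl = values[is_control].dropna()
    if len(ctrl) == 0:
        raise ValueError("at least one control sample with a defined value is required")
    if mode == "control-minimum":
        cutoff = float(ctrl.min())
    elif mode == "control-maximum":
        cutoff = float(ctrl.max())
    else:
        raise ValueError(f"mode must be 'control-minimum' or 'control-maximum', got {mode!r}")
    return CutoffRule(statistic=name or getattr(values, "name", "") or "", mode=mode, cutoff=cutoff)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson requires >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("pearson requires finite values")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def welch_t(a, b) -> tuple[float, float]:
    """Two-sided Welch t test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def welch_anova(*groups) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Uses the classical Welch (1951) statistic: weights w_i = n_i / s_i^2,
    F* = sum w_i (m_i - m_w)^2 / (k - 1) over a correction term, with
    approximate F(k-1, df2) reference distribution.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("welch_anova needs >= 2 groups")
    n = np.array([len(g) for g in gs], dtype=float)
    if (n < 2).any():
        raise ValueError("each group needs >= 2 values")
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    if (v <= 0).any():
        raise ValueError("each group needs positive variance")
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    den = 1.0 + 2.0 * (k - 2) / (k * k - 1.0) * lam
    f = num / den
    df1 = k - 1
    df2 = (k * k - 1.0) / (3.0 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p
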