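"""Kaplan-Meier estimation, log-rank testing and Cox proportional hazards
with IPSS-R ordinal coding and stepwise variable selection.

The Cox partial likelihood uses Breslow tie handling (Efron optional) and
is maximized by Newton-Raphson with step-halving; standard errors come
from the inverse observed information.  Clinical covariates can be
transformed to the ordinal codes defined by the IPSS-R cut-point ranges
(hemoglobin, platelets, neutrophils, marrow blasts, cytogenetic risk)
before entering a multivariate model, and forward-stepwise selection with
backward elimination retains only covariates that contribute
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from piwiflow.containers import PiwiflowError


class FitError(PiwiflowError):
    pass


# ---------------------------------------------------------------- Kaplan-Meier


@dataclass
class KMCurve:
    table: pd.DataFrame  # time, n_at_risk, n_events, n_censored, survival
    median: float  # NaN when S never reaches 0.5

    def survival_at(self, t: float) -> float:
        tab = self.table[self.table["time"] <= t]
        return 1.0 if tab.empty else float(tab["survival"].iloc[-1])


def km_curve(time, event) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    The median is the smallest observed time with S(t) <= 0.5 (NaN if the
    curve never reaches 0.5).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("km_curve requires at least one record")
    if (time <= 0).any() or not np.isfinite(time).all():
        raise ValueError("times must be finite and positive")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    n_at_risk = time.size
    for t in np.unique(time):
        mask = time == t
        d = int(event[mask].sum())
        c = int(mask.sum() - d)
        if d > 0:
            s *= 1.0 - d / n_at_risk
        rows.append((t, n_at_risk, d, c, s))
        n_at_risk -= int(mask.sum())
    table = pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "n_censored", "survival"])
    reached = table[table["survival"] <= 0.5 + 1e-12]
    median = float(reached["time"].iloc[0]) if not reached.empty else float("nan")
    return KMCurve(table=table, median=median)


def logrank(time, event, group) -> tuple[float, float]:
    """Two-sample log-rank test.

    Sums observed-minus-expected events in one stratum over event times
    with the hypergeometric variance; returns (chi-square, p) with 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"logrank requires exactly two strata, got {levels.size}")
    if event.sum() == 0:
        raise ValueError("logrank requires at least one event")
    in_a = group == levels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(event[(time == t)].sum())
        d_a = int(event[(time == t) & in_a].sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ------------------------------------------------------------------------ Cox


@dataclass
class CoxModel:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_events: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.exp(self.coef - 1.959963984540054 * self.se)
        hi = np.exp(self.coef + 1.959963984540054 * self.se)
        return lo, hi

    @property
    def p(self) -> np.ndarray:
        z = np.where(self.se > 0, self.coef / self.se, 0.0)
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci
        return pd.DataFrame(
            {"coef": self.coef, "HR": self.hr, "CI95_low": lo, "CI95_high": hi, "p": self.p},
            index=pd.Index(self.names, name="variable"),
        )


def _partial_lik_parts(beta: np.ndarray, x: np.ndarray, time: np.ndarray, event: np.ndarray,
                       ties: str) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and observed information (Breslow or
    Efron ties).  Iterates unique times in descending order, accumulating
    risk-set sums."""
    n, p = x.shape
    order = np.argsort(-time, kind="stable")
    xs, ts, es = x[order], time[order], event[order]
    xb = xs @ beta
    w = np.exp(xb)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        t = ts[i]
        while j < n and ts[j] == t:
            j += 1
        blk = slice(i, j)
        wb = w[blk]
        s0 += wb.sum()
        s1 += wb @ xs[blk]
        s2 += (xs[blk] * wb[:, None]).T @ xs[blk]
        ev = es[blk] == 1
        d = int(ev.sum())
        if d:
            xe = xs[blk][ev]
            ll += xb[blk][ev].sum()
            if ties == "breslow" or d == 1:
                ll -= d * np.log(s0)
                grad += xe.sum(axis=0) - d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
            elif ties == "efron":
                we = wb[ev]
                d0 = we.sum()
                d1 = we @ xe
                d2 = (xe * we[:, None]).T @ xe
                grad += xe.sum(axis=0)
                for r in range(d):
                    f = r / d
                    s0r = s0 - f * d0
                    s1r = s1 - f * d1
                    s2r = s2 - f * d2
                    ll -= np.log(s0r)
                    grad -= s1r / s0r
                    info += s2r / s0r - np.outer(s1r / s0r, s1r / s0r)
            else:
                raise ValueError(f"unknown tie method {ties!r}")
        i = j
    return ll, grad, info


def cox_fit(
    time,
    event,
    covariates: pd.DataFrame,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxModel:
    """Cox proportional-hazards fit by Newton-Raphson.

    Converges when the largest absolute coefficient change drops below
    ``tol``; raises :class:`FitError` (naming the worst covariate) on
    singular information, divergence, or non-convergence.
    """
    x = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if x.ndim != 2 or x.shape[0] != time.size:
        raise ValueError("covariate matrix and survival vectors are inconsistent")
    const = np.ptp(x, axis=0) == 0
    if const.any():
        raise FitError(f"covariate {names[int(np.argmax(const))]!r} is constant across samples")
    n_events = int(event.sum())
    if n_events < x.shape[1]:
        raise FitError("fewer events than covariates")

    beta = np.zeros(x.shape[1])
    ll, grad, info = _partial_lik_parts(beta, x, time, event, ties)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            worst = names[int(np.argmin(np.abs(np.diag(info))))]
            raise FitError(f"singular information matrix (covariate {worst!r})") from exc
        # step-halving to guarantee likelihood ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _partial_lik_parts(cand, x, time, event, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise FitError("step-halving failed to improve the partial likelihood")
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(beta)) > 50:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise FitError(f"monotone likelihood / diverging coefficient for {worst!r}")
        if delta < tol:
            break
    else:
        raise FitError(f"Newton-Raphson did not converge in {max_iter} iterations")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular information at the optimum") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return CoxModel(names=names, coef=beta, se=se, loglik=float(ll), n_events=n_events)


def cox_score_test(time, event, covariates: pd.DataFrame, ties: str = "breslow") -> tuple[float, float]:
    """Score (Rao) test of all coefficients = 0; for one binary covariate
    without ties this equals the log-rank statistic."""
    x = covariates.to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _, grad, info = _partial_lik_parts(np.zeros(x.shape[1]), x, time, event, ties)
    stat = float(grad @ np.linalg.solve(info, grad))
    return stat, float(stats.chi2.sf(stat, x.shape[1]))


# --------------------------------------------------------------------- IPSS-R

#: IPSS-R cut-point ranges; codes increase with clinical risk
IPSSR_CODES = {
    "hemoglobin": "g/dL: >=10 -> 0, 8-<10 -> 1, <8 -> 2",
    "platelets": "x10^9/L: >=100 -> 0, 50-<100 -> 1, <50 -> 2",
    "neutrophils": "x10^9/L: >=0.8 -> 0, <0.8 -> 1",
    "blasts": "%: <=2 -> 0, >2-<5 -> 1, 5-10 -> 2, >10 -> 3",
    "cytogenetics": "ordered risk category passed through as 0-4",
}


def ipssr_ordinalize(clinical: pd.DataFrame) -> pd.DataFrame:
    """Transform continuous clinical variables to IPSS-R ordinal codes.

    Expects columns hemoglobin (g/dL), platelets (x10^9/L), neutrophils
    (x10^9/L), blasts (%) and cytogenetics (ordered 0-4 code).
    """
    required = ["hemoglobin", "platelets", "neutrophils", "blasts", "cytogenetics"]
    missing = [c for c in required if c not in clinical.columns]
    if missing:
        raise KeyError(f"clinical table lacks required columns: {missing}")
    hb = clinical["hemoglobin"].to_numpy(dtype=float)
    plt = clinical["platelets"].to_numpy(dtype=float)
    anc = clinical["neutrophils"].to_numpy(dtype=float)
    bl = clinical["blasts"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "hemoglobin": np.select([hb < 8, hb < 10], [2, 1], default=0),
            "platelets": np.select([plt < 50, plt < 100], [2, 1], default=0),
            "neutrophils": np.where(anc < 0.8, 1, 0),
            "blasts": np.select([bl <= 2, bl < 5, bl <= 10], [0, 1, 2], default=3),
            "cytogenetics": clinical["cytogenetics"].to_numpy(dtype=int),
        },
        index=clinical.index,
    )
    return out


# ------------------------------------------------------------------- stepwise


def stepwise_cox(
    time,
    event,
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    ties: str = "breslow",
) -> CoxModel:
    """Forward-stepwise Cox selection with backward checks.

    Repeatedly adds the candidate with the smallest Wald p below
    ``p_enter`` (ties broken by candidate order), then removes any included
    covariate whose Wald p rises above ``p_remove``; stops when neither
    step changes the model.  Candidates whose trial fit fails (constant,
    collinear, diverging) are skipped.  May return an empty model.
    """
    if candidates.shape[1] < 2:
        raise ValueError("stepwise_cox expects >= 2 candidate covariates")
    included: list[str] = []
    # cycle guard: add/remove oscillations terminate after this many sweeps
    for _sweep in range(2 * candidates.shape[1] + 5):
        changed = False
        # forward step
        best_name, best_p = None, p_enter
        for name in candidates.columns:
            if name in included:
                continue
            trial = included + [name]
            try:
                model = cox_fit(time, event, candidates[trial], ties=ties)
            except (FitError, np.linalg.LinAlgError):
                continue
            p_new = model.p[-1]
            if p_new < best_p:
                best_name, best_p = name, p_new
        if best_name is not None:
            included.append(best_name)
            changed = True
        # backward checks
        while len(included) > 0:
            model = cox_fit(time, event, candidates[included], ties=ties)
            pvals = model.p
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                del included[worst]
                changed = True
            else:
                break
        if not changed:
            break
    if not included:
        return CoxModel(names=[], coef=np.zeros(0), se=np.zeros(0), loglik=float("nan"),
                        n_events=int(np.asarray(event).sum()))
    return cox_fit(time, event, candidates[included], ties=ties)
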