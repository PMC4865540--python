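"""Survival-statistics evaluation layer.

Kaplan-Meier estimation, log-rank tests, tertile grouping, Cox proportional
hazards with an ordinal trend test, ROC/Youden optimal cut-offs, and Pearson
correlation.  Kaplan-Meier, log-rank and Cox fits are delegated to lifelines
(Efron handling of ties); the trend test is the log-rank trend score test and
the ROC scan is explicit so that its decision rule (positive call at
``value >= cutoff``, candidate thresholds at midpoints of sorted distinct
values) is fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxFit",
    "RocResult",
    "km_estimate",
    "logrank",
    "logrank_trend",
    "tertile_groups",
    "cox_fit",
    "roc_optimal_cutoff",
    "pearson_r",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival curve as a right-continuous step function.

    ``times`` are the distinct observation times in ascending order,
    ``survival`` the estimate S(t) at each, ``n_at_risk`` the risk-set size
    just before each time.  ``at(0) == 1`` and the curve is non-increasing.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t) with the right-continuous step convention."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_surv(durations, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("survival input is empty")
    if t.shape != e.shape:
        raise ValueError("durations and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    return t, e


def km_estimate(durations, events) -> KMCurve:
    """Kaplan-Meier estimate of the survival function.

    Parameters
    ----------
    durations : array-like of float
        Follow-up times in years (must be positive).
    events : array-like of bool
        True if the endpoint (progression or death) occurred at ``durations``;
        False if censored then.
    """
    t, e = _check_surv(durations, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    timeline = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    # lifelines includes t=0 as the first row; keep it (at(0) = 1 by lookup).
    return KMCurve(times=timeline, survival=surv, n_at_risk=at_risk)


def logrank(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, float]:
    """Log-rank test across two or more groups.

    ``groups`` is a list of ``(durations, events)`` pairs.  Returns the
    chi-square statistic and its p-value (df = n_groups - 1).
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    ts, es, gs = [], [], []
    for i, (durations, events) in enumerate(groups):
        t, e = _check_surv(durations, events)
        ts.append(t)
        es.append(e)
        gs.append(np.full(t.shape, i))
    res = multivariate_logrank_test(np.concatenate(ts), np.concatenate(gs), np.concatenate(es))
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Tertiles


def tertile_groups(values) -> np.ndarray:
    """Assign each value to tertile group 1, 2 or 3.

    Boundaries are the empirical 1/3 and 2/3 quantiles; values equal to a
    boundary go to the lower group.  With fewer than three distinct values
    the split is degenerate: the assignment collapses and a warning is
    emitted.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("tertile grouping needs at least 3 values")
    if np.unique(v).size < 3:
        warnings.warn("fewer than 3 distinct values: degenerate tertile grouping", stacklevel=2)
    q1, q2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0])
    groups = np.ones(v.shape, dtype=int)
    groups[v > q1] = 2
    groups[v > q2] = 3
    return groups


# ---------------------------------------------------------------------------
# Cox regression


@dataclass
class CoxFit:
    """Per-level hazard ratios versus the lowest level plus an ordinal trend test."""

    levels: list
    n_per_level: dict
    events_per_level: dict
    hazard_ratios: dict  # level -> (hr, ci_low, ci_high); reference level -> (1.0, nan, nan)
    trend_chi2: float
    trend_p: float
    diagnostics: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for lv in self.levels:
            hr, lo, hi = self.hazard_ratios[lv]
            rows.append(
                {
                    "level": lv,
                    "n": self.n_per_level[lv],
                    "events": self.events_per_level[lv],
                    "HR": hr,
                    "CI95_low": lo,
                    "CI95_high": hi,
                }
            )
        df = pd.DataFrame(rows)
        df.attrs["trend_chi2"] = self.trend_chi2
        df.attrs["trend_p"] = self.trend_p
        return df


def logrank_trend(durations, events, scores) -> tuple[float, float]:
    """Log-rank trend test for ordered groups (score test at beta = 0).

    ``scores`` are ordinal scores (e.g. the tertile index).  At each distinct
    event time the observed sum of scores among the deaths is compared with
    its hypergeometric expectation over the risk set; the squared standardised
    total is chi-square with 1 df.  Equivalent to the Cox partial-likelihood
    score test for a single ordinal covariate.
    """
    t, e = _check_surv(durations, events)
    z = np.asarray(scores, dtype=float)
    u = 0.0
    v = 0.0
    for tj in np.unique(t[e]):
        at_risk = t >= tj
        nj = int(at_risk.sum())
        deaths = e & (t == tj)
        dj = int(deaths.sum())
        zbar = z[at_risk].mean()
        u += z[deaths].sum() - dj * zbar
        if nj > 1:
            var_z = float(((z[at_risk] - zbar) ** 2).mean())
            v += dj * (nj - dj) / (nj - 1) * var_z
    if v <= 0:
        return 0.0, 1.0
    chi2 = u * u / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_fit(durations, events, groups) -> CoxFit:
    """Cox proportional-hazards fit over an ordered categorical covariate.

    Levels are indicator-coded against the lowest level (Efron tie handling);
    the trend test treats the level index as a single ordinal score
    (:func:`logrank_trend`).  Requires at least two levels and at least one
    event overall; levels without events are flagged in ``diagnostics``
    (their HR estimates are unstable — quasi-separation).
    """
    t, e = _check_surv(durations, events)
    g = np.asarray(groups)
    levels = sorted(pd.unique(g).tolist())
    if len(levels) < 2:
        raise ValueError("cox_fit needs at least two covariate levels")
    if not e.any():
        raise ValueError("cox_fit needs at least one event")

    diagnostics: list[str] = []
    n_per = {lv: int((g == lv).sum()) for lv in levels}
    ev_per = {lv: int(e[g == lv].sum()) for lv in levels}
    for lv in levels:
        if ev_per[lv] == 0:
            diagnostics.append(f"level {lv!r} has no events (quasi-separation; HR unstable)")

    df = pd.DataFrame({"T": t, "E": e.astype(int)})
    cols = []
    for lv in levels[1:]:
        col = f"level_{lv}"
        df[col] = (g == lv).astype(float)
        cols.append(col)

    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="T", event_col="E")
    for w in caught:
        diagnostics.append(str(w.message))

    hrs = {levels[0]: (1.0, float("nan"), float("nan"))}
    ci = cph.confidence_intervals_
    with np.errstate(over="ignore"):  # CI bounds may overflow to inf under quasi-separation
        for lv, col in zip(levels[1:], cols):
            hrs[lv] = (
                float(np.exp(cph.params_[col])),
                float(np.exp(ci.loc[col].iloc[0])),
                float(np.exp(ci.loc[col].iloc[1])),
            )

    scores = np.array([levels.index(x) for x in g], dtype=float)
    chi2, p = logrank_trend(t, e, scores)
    return CoxFit(
        levels=levels,
        n_per_level=n_per,
        events_per_level=ev_per,
        hazard_ratios=hrs,
        trend_chi2=chi2,
        trend_p=p,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# ROC / Youden


@dataclass
class RocResult:
    """ROC scan with the Youden-optimal cut-off (positive call: value >= cutoff)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    optimal_cutoff: float
    sensitivity_at_optimum: float
    specificity_at_optimum: float
    youden: float


def roc_optimal_cutoff(values, outcome) -> RocResult:
    """Youden-optimal dichotomisation of a continuous marker.

    Candidate thresholds are the midpoints between sorted distinct values
    (plus open extremes); a subject is called positive when
    ``value >= cutoff`` and the positive class is ``outcome == True``.
    The optimum maximises J = sensitivity + specificity - 1; ties resolve to
    the lowest cut-off.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and outcome must be equal-length 1-D arrays")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")

    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    lo = distinct[0] - 1.0
    hi = distinct[-1] + 1.0
    thresholds = np.concatenate(([lo], mids, [hi]))

    sens = np.array([(v[y] >= c).mean() for c in thresholds])
    spec = np.array([(v[~y] < c).mean() for c in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (lowest) maximiser
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        optimal_cutoff=float(thresholds[best]),
        sensitivity_at_optimum=float(sens[best]),
        specificity_at_optimum=float(spec[best]),
        youden=float(j[best]),
    )


def cox_regression_table(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    factors: dict[str, str],
    multivariate: list[str] | None = None,
) -> pd.DataFrame:
    """Univariate (and optionally multivariate) Cox table over several factors.

    ``factors`` maps a display name to a column of ordered group labels.
    Each factor gets per-level HRs versus its lowest level with 95 % CIs and
    an ordinal trend chi-square.  Factors named in ``multivariate`` are
    additionally fitted jointly (indicator coding for the level HRs; one
    joint ordinal-score model for the adjusted trend chi-squares, Wald).
    """
    t = df[duration_col].to_numpy(dtype=float)
    e = df[event_col].to_numpy(dtype=bool)
    rows: list[dict] = []
    uni: dict[str, CoxFit] = {}
    for name, col in factors.items():
        uni[name] = cox_fit(t, e, df[col].to_numpy())

    mva_hr: dict[str, dict] = {}
    mva_trend: dict[str, tuple[float, float]] = {}
    if multivariate:
        joint = pd.DataFrame({"T": t, "E": e.astype(int)})
        dummy_cols: dict[str, list[tuple[object, str]]] = {}
        ord_joint = pd.DataFrame({"T": t, "E": e.astype(int)})
        for name in multivariate:
            g = df[factors[name]].to_numpy()
            levels = uni[name].levels
            dummy_cols[name] = []
            for lv in levels[1:]:
                col = f"{name}_{lv}"
                joint[col] = (g == lv).astype(float)
                dummy_cols[name].append((lv, col))
            ord_joint[name] = np.array([levels.index(x) for x in g], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(joint, duration_col="T", event_col="E")
            cph_ord = CoxPHFitter()
            cph_ord.fit(ord_joint, duration_col="T", event_col="E")
        ci = cph.confidence_intervals_
        for name in multivariate:
            mva_hr[name] = {}
            for lv, col in dummy_cols[name]:
                mva_hr[name][lv] = (
                    float(np.exp(cph.params_[col])),
                    float(np.exp(ci.loc[col].iloc[0])),
                    float(np.exp(ci.loc[col].iloc[1])),
                )
            z = cph_ord.params_[name] / cph_ord.standard_errors_[name]
            chi2 = float(z * z)
            mva_trend[name] = (chi2, float(stats.chi2.sf(chi2, df=1)))

    for name, fit in uni.items():
        for lv in fit.levels:
            hr, lo, hi = fit.hazard_ratios[lv]
            row = {
                "factor": name,
                "level": lv,
                "n": fit.n_per_level[lv],
                "events": fit.events_per_level[lv],
                "HR_uva": hr,
                "CI_low_uva": lo,
                "CI_high_uva": hi,
                "trend_chi2_uva": fit.trend_chi2,
                "trend_p_uva": fit.trend_p,
            }
            if name in mva_hr:
                ref = lv == fit.levels[0]
                mhr, mlo, mhi = (1.0, float("nan"), float("nan")) if ref else mva_hr[name][lv]
                row.update(
                    HR_mva=mhr,
                    CI_low_mva=mlo,
                    CI_high_mva=mhi,
                    trend_chi2_mva=mva_trend[name][0],
                    trend_p_mva=mva_trend[name][1],
                )
            rows.append(row)
    return pd.DataFrame(rows)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson_r needs equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r is undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
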