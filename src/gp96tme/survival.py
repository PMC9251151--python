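"""Right-censored survival machinery.

Kaplan–Meier estimation, the k-sample log-rank test and Efron-tie Cox
proportional-hazards fitting are delegated to lifelines; this module
additionally provides the signed standardized two-group log-rank
statistic, vectorized over many candidate group splits, which is the
computational core of the maximally-selected-rank cutpoint search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and >= 0")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return t, e.astype(int)


@dataclass
class KMCurve:
    """Product-limit survival estimate over the distinct observed times."""

    times: np.ndarray            # sorted distinct observed times
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    median_os: float             # inf when S never reaches 0.5
    n: int = 0
    total_events: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "at_risk": self.at_risk,
            "events": self.n_events,
            "survival": self.survival,
            "se": self.greenwood_se,
        })


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier estimate with Greenwood standard errors.

    The median OS is the first time at which S(t) <= 0.5 and is +inf when
    the curve never drops that far (e.g. all subjects censored).
    """
    t, e = _check_surv(times, events)
    if t.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    kmf = KaplanMeierFitter().fit(t, e)
    tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and t.min() > 0 \
        else kmf.event_table
    grid = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[grid, "KM_estimate"].to_numpy()
    n_at_risk = tab["at_risk"].to_numpy(dtype=int)
    d = tab["observed"].to_numpy(dtype=int)
    # Greenwood: var S(t) = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at_risk - d > 0, d / (n_at_risk * (n_at_risk - d)), np.nan)
        var = surv**2 * np.cumsum(np.nan_to_num(terms, nan=0.0))
    se = np.sqrt(var)
    se[surv == 0] = 0.0
    return KMCurve(
        times=grid, at_risk=n_at_risk, n_events=d, survival=surv,
        greenwood_se=se, median_os=float(kmf.median_survival_time_),
        n=int(t.size), total_events=int(e.sum()),
    )


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    group_sizes: dict = field(default_factory=dict)


def logrank_test(times, events, groups) -> LogrankResult:
    """k-sample log-rank chi-square test (df = k - 1)."""
    t, e = _check_surv(times, events)
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("logrank_test requires at least 2 non-empty groups")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=int(labels.size - 1),
        p_value=float(res.p_value),
        group_sizes={str(k): int(c) for k, c in zip(labels, counts)},
    )


@dataclass
class CoxResult:
    """Efron-tie Cox PH fit: one row per covariate plus model-level fields."""

    summary: pd.DataFrame        # beta, hr, se, ci95_low, ci95_high, wald_p
    log_likelihood: float
    converged: bool
    n: int
    n_events: int

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(times, events, covariates: pd.DataFrame) -> CoxResult:
    """Maximize the Efron partial likelihood by Newton iteration.

    Covariates with zero variance are reported as null effects
    (beta = 0, HR = 1) rather than entering the optimizer; perfect
    separation / monotone likelihood surfaces as an explicit error.
    """
    t, e = _check_surv(times, events)
    X = pd.DataFrame(covariates).reset_index(drop=True)
    if len(X) != t.size:
        raise ValueError("covariate rows must match number of subjects")
    if e.sum() < X.shape[1] + 1:
        raise ValueError(
            f"too few events ({e.sum()}) for {X.shape[1]} covariates")
    variable = [c for c in X.columns if X[c].nunique() > 1]
    rows = {}
    loglik, converged = 0.0, True
    if variable:
        df = X[variable].copy()
        df["_time"] = t
        df["_event"] = e
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as err:
            raise RuntimeError(
                "Cox fit did not converge (possible monotone likelihood / "
                f"perfect separation): {err}") from err
        s = cph.summary
        for c in variable:
            rows[c] = {
                "beta": float(s.loc[c, "coef"]),
                "hr": float(s.loc[c, "exp(coef)"]),
                "se": float(s.loc[c, "se(coef)"]),
                "ci95_low": float(np.exp(s.loc[c, "coef"] - 1.96 * s.loc[c, "se(coef)"])),
                "ci95_high": float(np.exp(s.loc[c, "coef"] + 1.96 * s.loc[c, "se(coef)"])),
                "wald_p": float(s.loc[c, "p"]),
            }
        loglik = float(cph.log_likelihood_)
    for c in X.columns:
        if c not in rows:  # constant covariate: no information, null effect
            rows[c] = {"beta": 0.0, "hr": 1.0, "se": math.inf,
                       "ci95_low": 0.0, "ci95_high": math.inf, "wald_p": 1.0}
    summary = pd.DataFrame(rows).T.loc[list(X.columns)]
    return CoxResult(summary=summary, log_likelihood=loglik,
                     converged=converged, n=int(t.size), n_events=int(e.sum()))


class LogrankScan:
    """Signed standardized two-group log-rank statistics for many splits.

    Precomputes the risk-set and death indicator matrices once for a fixed
    (times, events) sample so that the statistic can be evaluated cheaply
    for thousands of low-group masks (candidate cutpoints, permutations).
    The sign convention is (O - E)/sqrt(V) of the *low* group, with the
    standard hypergeometric variance summed over distinct event times.
    """

    def __init__(self, times, events):
        t, e = _check_surv(times, events)
        self.n = t.size
        self.event_times = np.unique(t[e == 1])
        self._atrisk = (t[:, None] >= self.event_times[None, :]).astype(float)
        self._death = ((t[:, None] == self.event_times[None, :])
                       & (e[:, None] == 1)).astype(float)
        self._Y = self._atrisk.sum(axis=0)
        self._d = self._death.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            self._factor = np.where(self._Y > 1,
                                    (self._Y - self._d) / (self._Y - 1), 0.0)

    def statistics(self, low_masks: np.ndarray) -> np.ndarray:
        """z for each column of ``low_masks`` (n × C boolean)."""
        L = np.atleast_2d(np.asarray(low_masks, dtype=float).T)  # C × n
        if self.event_times.size == 0:
            return np.zeros(L.shape[0])
        Y1 = L @ self._atrisk
        d1 = L @ self._death
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(self._Y > 0, Y1 / self._Y, 0.0)
        O = d1.sum(axis=1)
        E = (self._d * frac).sum(axis=1)
        V = (self._d * frac * (1.0 - frac) * self._factor).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(V > 0, (O - E) / np.sqrt(np.where(V > 0, V, 1.0)), 0.0)
        return z

    def statistic(self, low_mask: np.ndarray) -> float:
        return float(self.statistics(np.asarray(low_mask)[:, None])[0])
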