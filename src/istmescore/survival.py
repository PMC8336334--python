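"""Survival machinery: Kaplan-Meier, log-rank, Cox (Breslow ties), C-index.

Cox models use the Breslow tie approximation throughout (partial-likelihood
Newton fit via statsmodels PHReg); Kaplan-Meier and the log-rank test come
from lifelines; the concordance index is Harrell's estimator with risk ties
counted 0.5.  The sign convention for ``c_index`` is risk-like: higher risk
with shorter survival counts as concordant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from statsmodels.duration.hazard_regression import PHReg

from .containers import ClinicalTable


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray  # increasing event times
    survival: np.ndarray  # S(t) at those times, non-increasing
    at_risk: np.ndarray  # risk-set size just before each time
    n_events: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Per-covariate Wald statistics from a proportional-hazards fit."""

    names: list[str]
    beta: np.ndarray
    hr: np.ndarray
    se: np.ndarray
    p: np.ndarray
    log_likelihood: float
    n_events: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "hr": self.hr, "se": self.se, "p": self.p},
            index=self.names,
        )


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator (ties decrement simultaneously).

    With zero events the curve is flat at 1 (warned), mirroring a fully
    censored cohort.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    if events.sum() == 0:
        warnings.warn("no events observed; survival curve is flat at 1")
        return KMCurve(np.array([]), np.array([]), np.array([]), 0)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    surv = kmf.survival_function_at_times(event_times).values
    # risk set just before each event time
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return KMCurve(event_times, surv, at_risk, int(events.sum()))


def km_median(times, events) -> float:
    """Median survival time (inf when the curve never reaches 0.5)."""
    kmf = KaplanMeierFitter().fit(np.asarray(times, float), np.asarray(events, int))
    return float(kmf.median_survival_time_)


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """K-sample log-rank test; returns (chi2, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("log-rank test needs >=2 groups")
    res = multivariate_logrank_test(times, groups, events)
    df = len(levels) - 1
    return float(res.test_statistic), df, float(res.p_value)


def _phreg_fit(endog, status, exog, names) -> CoxFit:
    exog = np.asarray(exog, dtype=float)
    if exog.ndim == 1:
        exog = exog[:, None]
    for j, nm in enumerate(names):
        if np.ptp(exog[:, j]) == 0:
            raise ValueError(f"covariate {nm!r} is constant; Cox model not identifiable")
    if int(np.sum(status)) < 1:
        raise ValueError("no events; Cox model not identifiable")
    # fit on standardized covariates (same partial likelihood up to an exact
    # affine reparametrization) for Newton stability, then map back
    mu = exog.mean(axis=0)
    sd = exog.std(axis=0, ddof=0)
    model = PHReg(endog, (exog - mu) / sd, status=status, ties="breslow")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
        if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
            # Newton can overflow on heavy-tailed covariates; BFGS is slower
            # but robust
            res = model.fit(method="bfgs", disp=False)
    beta = np.asarray(res.params, float) / sd
    se = np.asarray(res.bse, float) / sd
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise RuntimeError(
            f"Cox fit did not converge (possible separation); params={beta}"
        )
    return CoxFit(
        names=list(names),
        beta=beta,
        hr=np.exp(beta),
        se=se,
        p=np.asarray(res.pvalues, float),
        log_likelihood=float(model.loglike(res.params)),
        n_events=int(np.sum(status)),
    )


def cox_univariate(x, clinical: ClinicalTable) -> CoxFit:
    """Univariate Cox PH fit of one per-sample covariate (Breslow ties)."""
    x = np.asarray(x, dtype=float)
    if len(x) != len(clinical.sample_ids):
        raise ValueError("covariate length does not match clinical table")
    if clinical.os_event.sum() < 2:
        raise ValueError("need >=2 events for a stable univariate Cox fit")
    return _phreg_fit(clinical.os_time, clinical.os_event, x, ["x"])


def cox_multivariate(
    clinical: ClinicalTable,
    covariates: list[str],
    reference_levels: dict[str, str] | None = None,
) -> CoxFit:
    """Multivariate Cox PH fit on named clinical columns (Breslow ties).

    Categorical covariates are dummy-coded against an explicit reference
    level (default: the lexicographically first level).
    """
    reference_levels = reference_levels or {}
    df = clinical.data
    cols = []
    names = []
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"covariate {cov!r} not in clinical table")
        col = df[cov]
        if np.issubdtype(col.dtype, np.number):
            cols.append(col.astype(float).values)
            names.append(cov)
        else:
            levels = sorted(col.astype(str).unique())
            ref = str(reference_levels.get(cov, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found for {cov!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((col.astype(str) == lev).astype(float).values)
                names.append(f"{cov}[{lev} vs {ref}]")
    exog = np.column_stack(cols)
    if clinical.os_event.sum() < exog.shape[1]:
        raise ValueError("fewer events than covariates; fit not identifiable")
    return _phreg_fit(clinical.os_time, clinical.os_event, exog, names)


def c_index(risk, times, events) -> float:
    """Harrell's concordance of a risk score with observed survival.

    Higher risk paired with shorter survival counts as concordant; tied
    risks count 0.5.  Raises when no usable pair exists.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    # lifelines scores "higher prediction -> longer survival"; negate risk.
    try:
        return float(concordance_index(times, -risk, events))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs for the concordance index") from exc
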