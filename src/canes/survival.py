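"""Marker-based survival utilities.

Samples are dichotomized into high/low expression groups at a user-chosen
quantile of a marker (multi-probe markers are summarized by the mean of
their member probes first).  Groups are compared by Kaplan-Meier curves and
the two-group log-rank test; Cox proportional-hazards regression on the
continuous (standardized) expression is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .datamodel import (
    CanesError,
    DegenerateSplitError,
    ExpressionDataset,
    resolve_markers,
)


def marker_expression(ds: ExpressionDataset, marker) -> np.ndarray:
    """Per-sample expression of a marker (mean over its member probes)."""
    ms = resolve_markers([marker] if isinstance(marker, str) else marker, ds)
    return ds.values[ms.indices].mean(axis=0)


def dichotomize(ds: ExpressionDataset, marker, cutoff_quantile: float = 0.5) -> np.ndarray:
    """Split samples into 'high'/'low' at a quantile of marker expression.

    High means strictly above the ``cutoff_quantile`` quantile over all
    samples.  Either group coming out empty (e.g. a constant marker) is a
    degenerate split.
    """
    if not 0 < cutoff_quantile < 1:
        raise CanesError("cutoff quantile must be in (0, 1)")
    expr = marker_expression(ds, marker)
    if np.isnan(expr).any():
        raise CanesError("marker expression contains missing values; impute first")
    cut = np.quantile(expr, cutoff_quantile)
    groups = np.where(expr > cut, "high", "low")
    if len(set(groups.tolist())) < 2:
        raise DegenerateSplitError(
            f"cutoff at quantile {cutoff_quantile} leaves one group empty "
            "(all values tied at the cutoff?)"
        )
    return groups


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations reduce the risk set without producing steps; with
    no censoring the estimate equals the empirical fraction surviving past t.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise CanesError("empty survival sample")
    if (times <= 0).any():
        raise CanesError("survival times must be positive")
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    steps = table[table["observed"] > 0]
    event_times = steps.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"]
    survival = np.array([float(surv.loc[t]) for t in steps.index])
    return KMCurve(
        event_times=event_times,
        at_risk=steps["at_risk"].to_numpy(dtype=int),
        events=steps["observed"].to_numpy(dtype=int),
        survival=survival,
    )


def logrank(times_a, events_a, times_b, events_b) -> tuple:
    """Two-group log-rank test: (chi2 statistic, upper-tail chi2_1 p-value).

    Standard hypergeometric variance with ties; symmetric in the two groups.
    """
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise CanesError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise CanesError("log-rank test needs at least one event")
    res = logrank_test(times_a, times_b, event_observed_A=events_a,
                       event_observed_B=events_b)
    chi2 = float(res.test_statistic)
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxResult:
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p: float
    log_hr: float
    converged: bool
    message: str = ""


def cox_fit(ds: ExpressionDataset, marker=None, groups=None,
            covariates: pd.DataFrame | None = None,
            standardize_marker: bool = True) -> CoxResult:
    """Cox proportional-hazards fit on a marker (or precomputed grouping).

    With ``marker`` given, the covariate of interest is its per-sample
    expression, standardized to unit SD by default so the hazard ratio is
    per SD of expression.  With ``groups`` given ('high'/'low'), a binary
    indicator (high = 1) is used.  Ties are handled by the Breslow
    convention.  Non-convergence or a degenerate covariate is reported in
    the result, not raised.
    """
    if ds.survival is None:
        raise CanesError("dataset has no survival annotation")
    surv = ds.survival.reindex(ds.sample_ids)
    if surv["time"].isna().any():
        raise CanesError("survival information missing for some samples")

    if groups is not None:
        x = (np.asarray(groups) == "high").astype(float)
        name = "high_expression"
    elif marker is not None:
        x = marker_expression(ds, marker)
        if standardize_marker:
            s = x.std()
            if s > 0:
                x = (x - x.mean()) / s
        name = str(marker)
    else:
        raise CanesError("provide a marker or a group assignment")
    if np.std(x) == 0:
        return CoxResult(float("nan"), float("nan"), float("nan"), float("nan"),
                         float("nan"), converged=False,
                         message="constant covariate; fit is degenerate")

    frame = pd.DataFrame({"time": surv["time"].to_numpy(),
                          "event": surv["event"].to_numpy(), name: x})
    if covariates is not None:
        frame = pd.concat([frame, covariates.reset_index(drop=True)], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError and others
        return CoxResult(float("nan"), float("nan"), float("nan"), float("nan"),
                         float("nan"), converged=False, message=str(exc))
    log_hr = float(cph.params_[name])
    ci = cph.confidence_intervals_.loc[name]
    return CoxResult(
        hazard_ratio=float(np.exp(log_hr)),
        ci_lower=float(np.exp(ci.iloc[0])),
        ci_upper=float(np.exp(ci.iloc[1])),
        p=float(cph.summary.loc[name, "p"]),
        log_hr=log_hr,
        converged=True,
    )


def survival_analysis(ds: ExpressionDataset, marker, cutoff_quantile: float = 0.5):
    """KM curves per expression group, log-rank test, and Cox fit.

    Returns a dict with 'groups', 'km' (group -> KMCurve), 'logrank'
    (chi2, p), and 'cox' (CoxResult on the continuous marker).
    """
    if ds.survival is None:
        raise CanesError("dataset has no survival annotation")
    groups = dichotomize(ds, marker, cutoff_quantile)
    surv = ds.survival.reindex(ds.sample_ids)
    times = surv["time"].to_numpy(float)
    events = surv["event"].to_numpy(int)
    hi, lo = groups == "high", groups == "low"
    km = {
        "high": km_estimate(times[hi], events[hi]),
        "low": km_estimate(times[lo], events[lo]),
    }
    chi2, p = logrank(times[hi], events[hi], times[lo], events[lo])
    cox = cox_fit(ds, marker=marker)
    return {"groups": groups, "km": km, "logrank": (chi2, p), "cox": cox}
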