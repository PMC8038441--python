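"""Cutoff-based prognostic stratification.

High/low groups are formed by an absolute expression cutoff (high iff
TPM >= cutoff); the two (or k) groups are then compared with Kaplan–Meier
curves, the unweighted log-rank test, and a univariate Cox proportional-
hazards ratio with a Wald 95% CI.  The same machinery runs overall and
within each EMT phenotype.

Kaplan–Meier, log-rank and Cox fits are delegated to lifelines; this
module owns the stratification rules, the result contracts, and the
non-estimability handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .dataio import ExpressionMatrix
from .emt import PHENOTYPES
from .errors import InsufficientCohortError, NonEstimableError


def stratify_by_cutoff(values, cutoff: float):
    """Label each sample 'high' (value >= cutoff) or 'low' (value < cutoff).

    Returns ``(labels, high_fraction)``; ``labels`` is a Series when the
    input carries an index.
    """
    ser = pd.Series(values, dtype=float)
    if not np.isfinite(ser).all():
        raise ValueError("stratify_by_cutoff needs finite values")
    labels = pd.Series(np.where(ser >= cutoff, "high", "low"), index=ser.index)
    return labels, float((labels == "high").mean())


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve with right censoring.

    Returns a DataFrame with one row per distinct event time (plus t=0):
    time, survival, at_risk, events.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise InsufficientCohortError("km_estimate needs at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "time": tab.index.to_numpy(dtype=float),
        "survival": surv.reindex(tab.index).to_numpy(dtype=float),
        "at_risk": tab["at_risk"].to_numpy(dtype=int),
        "events": tab["observed"].to_numpy(dtype=int),
    })
    return out.reset_index(drop=True)


def logrank_test(times, events, groups):
    """Unweighted k-group log-rank test; returns (statistic, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise InsufficientCohortError("log-rank test needs >= 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    df = len(levels) - 1
    return float(res.test_statistic), int(df), float(min(res.p_value, 1.0))


def hazard_ratio(times, events, binary_group):
    """Univariate Cox proportional-hazards HR with a Wald 95% CI.

    ``binary_group`` is 0/1 (or boolean) exposure.  The partial likelihood
    is maximised by Newton iteration (lifelines, Breslow tie handling);
    the CI is the Wald interval on the log scale, exponentiated.

    Returns ``(hr, ci_lo, ci_hi)``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(binary_group, dtype=int)
    if set(np.unique(group)) - {0, 1}:
        raise ValueError("binary_group must be 0/1")
    if len(np.unique(group)) < 2:
        raise NonEstimableError("both exposure groups must be non-empty")
    if events.sum() == 0:
        raise NonEstimableError("no events observed; hazard ratio non-estimable")
    if events[group == 0].sum() == 0 or events[group == 1].sum() == 0:
        raise NonEstimableError(
            "all events fall in one exposure group; partial likelihood separates"
        )
    df = pd.DataFrame({"time": times, "event": events, "group": group})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-10})
    except ConvergenceError as e:
        raise NonEstimableError(f"Cox fit did not converge: {e}") from e
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    hr = float(np.exp(beta))
    lo, hi = float(np.exp(beta - 1.959963984540054 * se)), \
             float(np.exp(beta + 1.959963984540054 * se))
    return hr, lo, hi


@dataclass
class SurvivalResult:
    """Two-group survival comparison within one stratum."""

    label: str
    n_per_group: dict
    km_curves: dict            # group -> km_estimate DataFrame
    logrank_stat: float | None
    logrank_p: float | None
    hr: float | None
    hr_ci: tuple[float, float] | None
    estimable: bool
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_per_group": self.n_per_group,
            "estimable": self.estimable,
            "logrank_stat": self.logrank_stat,
            "logrank_p": self.logrank_p,
            "hr": self.hr,
            "hr_ci": list(self.hr_ci) if self.hr_ci else None,
            "note": self.note,
            "km_curves": {g: c.to_dict(orient="list")
                          for g, c in self.km_curves.items()},
        }


def compare_two_groups(times, events, labels, stratum: str = "overall") -> SurvivalResult:
    """KM + log-rank + HR for a high/low labelled sample set.

    Degenerate strata (an empty group, no events, or complete separation)
    come back flagged non-estimable instead of raising.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    n_per = {g: int((labels == g).sum()) for g in ("high", "low")}
    curves = {g: km_estimate(times[labels == g], events[labels == g])
              for g in ("high", "low") if n_per[g] > 0}
    if min(n_per.values()) == 0:
        return SurvivalResult(stratum, n_per, curves, None, None, None, None,
                              estimable=False, note="one stratum is empty")
    stat, _df, p = logrank_test(times, events, labels)
    try:
        hr, lo, hi = hazard_ratio(times, events, (labels == "high").astype(int))
        return SurvivalResult(stratum, n_per, curves, stat, p, hr, (lo, hi),
                              estimable=True)
    except NonEstimableError as e:
        return SurvivalResult(stratum, n_per, curves, stat, p, None, None,
                              estimable=False, note=str(e))


def per_phenotype_survival(expr: ExpressionMatrix, clinical: pd.DataFrame,
                           calls: pd.DataFrame, feature_id: str,
                           cutoff: float) -> list[SurvivalResult]:
    """High-vs-low cutoff comparison of survival within each EMT phenotype.

    Always returns exactly four results, ordered as :data:`PHENOTYPES`;
    phenotypes where either stratum is empty are flagged non-estimable.
    """
    clin = clinical.set_index("sample_id").reindex(expr.sample_ids)
    if clin["time"].isna().any():
        missing = clin.index[clin["time"].isna()].tolist()
        raise InsufficientCohortError(f"clinical data missing for samples {missing}")
    labels, _frac = stratify_by_cutoff(expr.feature(feature_id), cutoff)
    results = []
    for ph in PHENOTYPES:
        mask = (calls["phenotype"] == ph).reindex(expr.sample_ids, fill_value=False)
        sub = clin[mask.to_numpy()]
        sub_labels = labels[mask.to_numpy()]
        if len(sub) == 0:
            results.append(SurvivalResult(ph, {"high": 0, "low": 0}, {}, None, None,
                                          None, None, estimable=False,
                                          note="phenotype has no samples"))
            continue
        results.append(compare_two_groups(sub["time"], sub["event"],
                                          sub_labels, stratum=ph))
    return results
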