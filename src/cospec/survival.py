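"""Survival stratification of pattern-classified patients.

Kaplan-Meier curves and medians, the two-group log-rank test, Cox
proportional-hazards fits (univariate, or bivariate with tumor stage) with
Harrell's concordance, and PFS-conditioned record subsets.  Estimators are
delegated to lifelines (product-limit estimator, chi-square log-rank,
partial likelihood with Efron tie handling); this module owns the contract:
deterministic medians (undefined when the curve never reaches 0.5), hazard
ratios with 95% confidence intervals, and the record bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io import SurvivalRecord


@dataclass
class KMCurve:
    label: str
    times: np.ndarray  # event/censor times in months
    events: np.ndarray
    step_times: np.ndarray  # times where the survival function steps
    survival: np.ndarray  # S(t) just after each step time
    median_survival_months: float | None
    n: int
    n_events: int


@dataclass
class CoxFit:
    covariates: list[str]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    concordance: float
    n: int
    events: int


def _arrays(records: "list[SurvivalRecord]") -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.os_months for r in records], dtype=float)
    e = np.array([r.os_event for r in records], dtype=bool)
    return t, e


def km_curves(
    records: "list[SurvivalRecord]", groups: "dict[str, str]"
) -> list[KMCurve]:
    """Product-limit survival curve per group (groups maps patient -> label).

    The median is the earliest time at which S(t) <= 0.5 and is undefined
    (None) when the curve ends above 0.5.
    """
    by_label: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        if r.patient_id in groups:
            by_label.setdefault(groups[r.patient_id], []).append(r)
    if not by_label or any(len(v) == 0 for v in by_label.values()):
        raise ValueError("every group must contain at least one record")
    curves = []
    for label in sorted(by_label):
        recs = by_label[label]
        t, e = _arrays(recs)
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e)
        med = kmf.median_survival_time_
        median = None if np.isinf(med) else float(med)
        sf = kmf.survival_function_
        curves.append(
            KMCurve(
                label=label,
                times=t,
                events=e,
                step_times=sf.index.to_numpy(dtype=float),
                survival=sf.iloc[:, 0].to_numpy(dtype=float),
                median_survival_months=median,
                n=len(recs),
                n_events=int(e.sum()),
            )
        )
    return curves


def logrank(
    records: "list[SurvivalRecord]", groups: "dict[str, str]"
) -> dict[str, float | None]:
    """Two-group log-rank test (1 df chi-square, two-sided P).

    Returns {"statistic": ..., "p_value": ...}; both None when no events
    occurred.  Invariant under swapping the two group labels.
    """
    labeled = [r for r in records if r.patient_id in groups]
    labels = sorted({groups[r.patient_id] for r in labeled})
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {labels}")
    a = [r for r in labeled if groups[r.patient_id] == labels[0]]
    b = [r for r in labeled if groups[r.patient_id] == labels[1]]
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    ta, ea = _arrays(a)
    tb, eb = _arrays(b)
    if ea.sum() + eb.sum() == 0:
        return {"statistic": None, "p_value": None}
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return {"statistic": float(res.test_statistic), "p_value": float(res.p_value)}


def cox_fit(
    records: "list[SurvivalRecord]",
    covariates: "dict[str, dict[str, float]]",
) -> CoxFit:
    """Cox proportional-hazards fit with Efron tie handling.

    ``covariates`` maps covariate name -> {patient_id: value}; one entry
    gives a univariate fit, two (e.g. pattern_high and stage) a bivariate
    one.  Records missing any covariate are dropped.  Returns hazard ratios
    with 95% confidence intervals and Harrell's concordance index.
    """
    if not 1 <= len(covariates) <= 2:
        raise ValueError("provide one or two covariates")
    names = list(covariates)
    rows = []
    for r in records:
        vals = [covariates[c].get(r.patient_id) for c in names]
        if any(v is None for v in vals):
            continue
        rows.append([r.os_months, int(r.os_event), *[float(v) for v in vals]])
    df = pd.DataFrame(rows, columns=["os_months", "os_event", *names])
    n, events = len(df), int(df["os_event"].sum())
    for c in names:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant among fitted records")
    if events < len(names) + 1:
        raise ValueError(f"only {events} events for {len(names)} covariate(s)")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="os_months", event_col="os_event")
    except Exception as exc:  # lifelines raises ConvergenceError and warnings
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summary = cph.summary
    return CoxFit(
        covariates=names,
        hazard_ratios={c: float(summary.loc[c, "exp(coef)"]) for c in names},
        ci_lower={c: float(summary.loc[c, "exp(coef) lower 95%"]) for c in names},
        ci_upper={c: float(summary.loc[c, "exp(coef) upper 95%"]) for c in names},
        concordance=float(cph.concordance_index_),
        n=n,
        events=events,
    )


def pfs_subset(
    records: "list[SurvivalRecord]", min_pfs_months: float
) -> list[SurvivalRecord]:
    """Records whose recorded PFS is at least the threshold.

    Records without a PFS value are excluded, so ``pfs_subset(records, 0)``
    is "all patients who experienced PFS >= 0 months".  Monotone:
    larger thresholds give nested subsets.
    """
    return [
        r
        for r in records
        if r.pfs_months is not None and r.pfs_months >= min_pfs_months
    ]
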