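"""Kaplan-Meier estimation and log-rank comparison across IHC groups.

Endpoints follow the cystectomy-cohort conventions: progression-free
survival (PFS) runs from cystectomy to detected progression or right-censor,
overall survival (OS) to death or right-censor, both in months.  Groups can
be two-marker immunophenotypes, significant-cluster labels, or the
unilateral/bilateral nodal pattern.  Estimation and testing are delegated to
lifelines; this module owns the dataset assembly and the result surfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .classify import SubtypeCall
from .datamodel import ClinicalRecord, LesionSite, ValidationError

logger = logging.getLogger(__name__)

ENDPOINTS = ("pfs", "os")
GROUPINGS = ("two_marker", "cluster", "nodal_pattern")


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray  # ordered distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    greenwood_var: np.ndarray  # Greenwood variance of S(t) at each step
    n_subjects: int
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "greenwood_var": self.greenwood_var,
            }
        )


def km_estimate(
    times: np.ndarray, events: np.ndarray, group: str = ""
) -> KMCurve:
    """Kaplan-Meier curve for one group.

    ``times`` are positive follow-up times; ``events`` flags observed events
    (False = right-censored).  Ties between an event and a censoring at the
    same time follow the standard convention: the censored subject is still
    at risk for the event (censoring applied after events).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError(["empty survival group"])
    if (times <= 0).any():
        raise ValidationError(["non-positive survival times"])
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table  # indexed by time: removed, observed, at_risk...
    event_rows = table[table["observed"] > 0]
    d = event_rows["observed"].to_numpy(dtype=float)
    n = event_rows["at_risk"].to_numpy(dtype=float)
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_rows.index]
    )
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d))), over event times only
    increments = np.divide(d, n * (n - d), out=np.zeros_like(d), where=(n - d) > 0)
    greenwood = surv**2 * np.cumsum(increments)
    return KMCurve(
        group=group,
        times=event_rows.index.to_numpy(dtype=float),
        survival=surv,
        at_risk=n,
        greenwood_var=greenwood,
        n_subjects=int(times.size),
        n_events=int(events.sum()),
    )


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(dataset: pd.DataFrame) -> LogrankResult:
    """Unweighted k-group log-rank test on a (time, event, group) dataset.

    Requires at least two non-empty groups and at least one event overall
    (the statistic is undefined without events).
    """
    required = {"time", "event", "group"}
    if not required <= set(dataset.columns):
        raise ValidationError([f"survival dataset needs columns {sorted(required)}"])
    groups = dataset["group"].unique()
    if len(groups) < 2:
        raise ValidationError(["log-rank needs at least 2 groups"])
    if int(dataset["event"].sum()) == 0:
        raise ValidationError(["log-rank undefined with zero events"])
    res = multivariate_logrank_test(
        dataset["time"], dataset["group"], dataset["event"]
    )
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
    )


def assemble_survival(
    clinical: list[ClinicalRecord],
    calls: list[SubtypeCall] | None = None,
    endpoint: str = "pfs",
    grouping: str = "two_marker",
    cluster_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build the (patient_id, time, event, group) dataset for one comparison.

    ``grouping``:

    * ``two_marker`` — group by the primary lesion's two-marker call;
    * ``cluster`` — group by significant-cluster label (``cluster_labels``
      maps patient_id -> label; patients left unassigned by the bootstrap
      clustering are excluded, with a logged warning);
    * ``nodal_pattern`` — unilateral vs bilateral nodal metastasis.
    """
    if endpoint not in ENDPOINTS:
        raise ValidationError([f"unknown endpoint {endpoint!r}"])
    if grouping not in GROUPINGS:
        raise ValidationError([f"unknown grouping {grouping!r}"])

    if grouping == "two_marker":
        if calls is None:
            raise ValidationError(["two_marker grouping needs subtype calls"])
        group_of = {
            c.patient_id: c.major for c in calls if c.lesion_site == LesionSite.PRIMARY
        }
    elif grouping == "cluster":
        if cluster_labels is None:
            raise ValidationError(["cluster grouping needs cluster_labels"])
        group_of = dict(cluster_labels)
    else:
        group_of = {c.patient_id: c.nodal_pattern for c in clinical}

    rows, dropped = [], []
    for record in clinical:
        group = group_of.get(record.patient_id)
        if group is None:
            dropped.append(record.patient_id)
            continue
        time = record.pfs_time if endpoint == "pfs" else record.os_time
        event = record.pfs_event if endpoint == "pfs" else record.os_event
        rows.append(
            {
                "patient_id": record.patient_id,
                "time": time,
                "event": bool(event),
                "group": group,
            }
        )
    if dropped:
        logger.warning(
            "%d patients without a %s group excluded from survival analysis: %s",
            len(dropped),
            grouping,
            sorted(dropped),
        )
    if not rows:
        raise ValidationError(["no patients left after grouping"])
    return pd.DataFrame(rows)


def km_by_group(dataset: pd.DataFrame) -> list[KMCurve]:
    """One Kaplan-Meier curve per group of an assembled dataset."""
    return [
        km_estimate(sub["time"].to_numpy(), sub["event"].to_numpy(), group=str(name))
        for name, sub in dataset.groupby("group", sort=True)
    ]
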