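"""Synthetic MIUC cohort simulator.

Generates cohorts with the statistical structure the downstream analysis
assumes: a latent immunophenotype per patient (luminal/basal/mixed plus the
rare CK20+/CK18- reject pattern), subtype-conditional Beta distributions for
marker percent positivity, a unilateral/bilateral nodal pattern, a
row-stochastic transition matrix giving each nodal metastasis' subtype
conditional on the primary, and per-subtype exponential PFS/OS hazards with
independent uniform right-censoring.  The latent truth table is returned so
recovery tests can compare estimates against the generating parameters.

Markers are conditionally independent given the subtype (a documented
simplification); expressed markers draw percent/100 ~ Beta(8, 2) (mean 80%)
and silent markers ~ Beta(1, 20) (mean ~4.8%), separated enough that the
20% cutoff misreads a marker's status in ~1% of lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import SUBTYPES
from .datamodel import (
    MARKER_PANEL,
    ClinicalRecord,
    CohortMatrix,
    IHCLesionRecord,
    LesionSite,
    MarkerScore,
)

#: Markers expressed by each latent subtype; everything else is silent.
POSITIVE_MARKERS: dict[str, tuple[str, ...]] = {
    "luminal": ("UPK", "GATA3", "CK18", "CK20"),
    "mixed": ("GATA3", "CK5", "CK18"),
    "basal": ("CK5", "CK14", "CD44"),
    "unclassified": ("CK20",),  # the CK20+/CK18- reject pattern
}

DEFAULT_POSITIVE_BETA = (8.0, 2.0)
DEFAULT_NEGATIVE_BETA = (1.0, 20.0)


def default_marker_beta_params() -> dict[tuple[str, str], tuple[float, float]]:
    """(subtype, marker) -> Beta(alpha, beta) for percent/100."""
    return {
        (subtype, marker): (
            DEFAULT_POSITIVE_BETA
            if marker in POSITIVE_MARKERS[subtype]
            else DEFAULT_NEGATIVE_BETA
        )
        for subtype in SUBTYPES
        for marker in MARKER_PANEL
    }


def default_transition_matrix() -> pd.DataFrame:
    """P(metastasis subtype | primary subtype), rows = primary.

    Defaults transcribe the observed cross-classification frequencies of the
    motivating 38-patient institutional cohort (per-row counts 11/10/16/1).
    """
    rows = {
        "luminal": [10 / 11, 1 / 11, 0.0, 0.0],
        "basal": [1 / 10, 6 / 10, 3 / 10, 0.0],
        "mixed": [3 / 16, 1 / 16, 12 / 16, 0.0],
        "unclassified": [0.0, 0.0, 1.0, 0.0],
    }
    return pd.DataFrame(
        [rows[s] for s in SUBTYPES],
        index=pd.Index(SUBTYPES, name="primary"),
        columns=pd.Index(SUBTYPES, name="metastasis"),
    )


@dataclass
class SyntheticCohortConfig:
    """All simulator parameters; (config, seed) fully determines the output."""

    n_patients: int = 38
    subtype_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "luminal": 11 / 38,
            "basal": 10 / 38,
            "mixed": 16 / 38,
            "unclassified": 1 / 38,
        }
    )
    marker_beta_params: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=default_marker_beta_params
    )
    intensity_thresholds: tuple[float, float] = (33.0, 66.0)
    nodal_pattern_probs: dict[str, float] = field(
        default_factory=lambda: {"unilateral": 23 / 38, "bilateral": 15 / 38}
    )
    p_right_given_unilateral: float = 11 / 23
    transition_matrix: pd.DataFrame = field(default_factory=default_transition_matrix)
    # monthly exponential hazards; basal < mixed < luminal for PFS (basal
    # carried the better progression-free prognosis in the motivating cohort)
    pfs_hazard: dict[str, float] = field(
        default_factory=lambda: {
            "luminal": 0.08,
            "mixed": 0.05,
            "basal": 0.03,
            "unclassified": 0.05,
        }
    )
    os_hazard: dict[str, float] = field(
        default_factory=lambda: {
            "luminal": 0.05,
            "mixed": 0.035,
            "basal": 0.025,
            "unclassified": 0.035,
        }
    )
    censoring_window_months: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        errors: list[str] = []
        if self.n_patients < 1:
            errors.append("n_patients must be >= 1")
        mix = [self.subtype_mixture.get(s, 0.0) for s in SUBTYPES]
        if abs(sum(mix) - 1.0) > 1e-12 or min(mix) < 0:
            errors.append(f"subtype mixture must be a probability vector; got {mix}")
        pats = [self.nodal_pattern_probs.get(k, 0.0) for k in ("unilateral", "bilateral")]
        if abs(sum(pats) - 1.0) > 1e-12 or min(pats) < 0:
            errors.append("nodal pattern probabilities must sum to 1")
        if not 0 <= self.p_right_given_unilateral <= 1:
            errors.append("p_right_given_unilateral outside [0, 1]")
        T = self.transition_matrix
        if list(T.index) != list(SUBTYPES) or list(T.columns) != list(SUBTYPES):
            errors.append("transition matrix must be indexed by the 4 subtypes")
        else:
            bad = [
                s
                for s in SUBTYPES
                if abs(T.loc[s].sum() - 1.0) > 1e-12 or (T.loc[s] < 0).any()
            ]
            if bad:
                errors.append(f"transition rows not stochastic: {bad}")
        for (subtype, marker), (a, b) in self.marker_beta_params.items():
            if a <= 0 or b <= 0:
                errors.append(f"Beta params for {(subtype, marker)} must be > 0")
        for name, hazards in (("pfs", self.pfs_hazard), ("os", self.os_hazard)):
            if any(h <= 0 for h in hazards.values()):
                errors.append(f"{name} hazards must be > 0")
        if self.censoring_window_months <= 0:
            errors.append("censoring window must be > 0")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class SimulatedCohort:
    ihc_records: list[IHCLesionRecord]
    clinical_records: list[ClinicalRecord]
    truth: pd.DataFrame  # latent subtypes, met subtypes, uncensored times


def _intensity(percent: float, thresholds: tuple[float, float]) -> int:
    if percent == 0:
        return 0
    if percent <= thresholds[0]:
        return 1
    if percent <= thresholds[1]:
        return 2
    return 3


def _draw_lesion(
    rng: np.random.Generator,
    config: SyntheticCohortConfig,
    patient_id: str,
    site: LesionSite,
    subtype: str,
) -> IHCLesionRecord:
    scores = {}
    for marker in MARKER_PANEL:
        a, b = config.marker_beta_params[(subtype, marker)]
        percent = 100.0 * float(rng.beta(a, b))
        scores[marker] = MarkerScore(percent, _intensity(percent, config.intensity_thresholds))
    return IHCLesionRecord(patient_id, site, scores)


def simulate_cohort(config: SyntheticCohortConfig) -> SimulatedCohort:
    """Simulate one cohort; bit-reproducible given (config, config.seed).

    Each patient consumes an independent substream keyed by (seed, index),
    so enlarging the cohort never perturbs earlier patients' draws, and the
    censoring time is ``window * u`` with ``u`` drawn before scaling, so
    widening the follow-up window on the same seed can only convert censored
    subjects into events, never the reverse.
    """
    config.validate()
    mixture = np.array([config.subtype_mixture[s] for s in SUBTYPES])
    p_bilateral = config.nodal_pattern_probs["bilateral"]
    T = config.transition_matrix.to_numpy()

    ihc: list[IHCLesionRecord] = []
    clinical: list[ClinicalRecord] = []
    truth_rows = []
    width = max(4, len(str(config.n_patients)))
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        pid = f"S{i + 1:0{width}d}"

        subtype = SUBTYPES[rng.choice(len(SUBTYPES), p=mixture)]
        bilateral = bool(rng.random() < p_bilateral)
        right_side = bool(rng.random() < config.p_right_given_unilateral)
        row = T[SUBTYPES.index(subtype)]
        met_sites: list[LesionSite]
        if bilateral:
            met_sites = [LesionSite.NODE_RIGHT, LesionSite.NODE_LEFT]
        else:
            met_sites = [LesionSite.NODE_RIGHT if right_side else LesionSite.NODE_LEFT]
        met_subtypes = {
            site: SUBTYPES[rng.choice(len(SUBTYPES), p=row)] for site in met_sites
        }

        ihc.append(_draw_lesion(rng, config, pid, LesionSite.PRIMARY, subtype))
        for site in met_sites:
            ihc.append(_draw_lesion(rng, config, pid, site, met_subtypes[site]))

        t_prog = float(rng.exponential(1.0 / config.pfs_hazard[subtype]))
        t_death = float(rng.exponential(1.0 / config.os_hazard[subtype]))
        censor_u = float(rng.random())
        censor = config.censoring_window_months * (1.0 - censor_u)  # in (0, window]
        pfs_raw = min(t_prog, t_death)
        pfs_time, pfs_event = min(pfs_raw, censor), pfs_raw <= censor
        os_time, os_event = min(t_death, censor), t_death <= censor

        age = float(np.clip(rng.normal(67.8, 5.0), 45.0, 92.0))
        sex = "M" if rng.random() < 33 / 38 else "F"
        stage = ["T2", "T3", "T4"][rng.choice(3, p=np.array([4, 19, 15]) / 38)]
        treatment = [
            "cystectomy",
            "cystectomy+CT",
            "cystectomy+IT",
            "cystectomy+CT+IT",
            "cystectomy+RT",
        ][rng.choice(5, p=np.array([30, 4, 2, 1, 1]) / 38)]

        clinical.append(
            ClinicalRecord(
                patient_id=pid,
                age_years=round(age, 1),
                sex=sex,
                pt_stage=stage,
                nodal_pattern="bilateral" if bilateral else "unilateral",
                treatment=treatment,
                pfs_time=pfs_time,
                pfs_event=pfs_event,
                os_time=os_time,
                os_event=os_event,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "primary_subtype": subtype,
                "nodal_pattern": "bilateral" if bilateral else "unilateral",
                "met_right_subtype": met_subtypes.get(LesionSite.NODE_RIGHT),
                "met_left_subtype": met_subtypes.get(LesionSite.NODE_LEFT),
                "t_prog": t_prog,
                "t_death": t_death,
                "censor_time": censor,
            }
        )

    return SimulatedCohort(
        ihc_records=ihc,
        clinical_records=clinical,
        truth=pd.DataFrame(truth_rows),
    )


def planted_block_matrix(
    block_sizes: dict[str, int],
    seed: int = 0,
    marker_beta_params: dict[tuple[str, str], tuple[float, float]] | None = None,
) -> tuple[CohortMatrix, dict[str, list[str]]]:
    """Cohort matrix with exact per-subtype block sizes (no mixture sampling).

    Useful for planted-cluster recovery experiments where the block
    membership must be known and fixed.  Returns the matrix and the mapping
    subtype -> member patient ids.
    """
    params = marker_beta_params or default_marker_beta_params()
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    rows: list[list[float]] = []
    membership: dict[str, list[str]] = {}
    for subtype, size in block_sizes.items():
        members = []
        for k in range(size):
            pid = f"{subtype[:3].upper()}{k + 1:02d}"
            row = [
                100.0 * float(rng.beta(*params[(subtype, m)])) for m in MARKER_PANEL
            ]
            ids.append(pid)
            rows.append(row)
            members.append(pid)
        membership[subtype] = members
    return CohortMatrix(values=np.array(rows), patient_ids=ids), membership
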