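"""Core data model for semiquantitative IHC scoring of muscle-invasive
urothelial carcinoma (MIUC) cohorts.

A lesion (primary bladder tumor or a pelvic lymph-node metastasis) is scored
on a fixed seven-marker panel: each marker gets a percent of positive tumor
cells (0-100) and an ordinal staining intensity (0 = negative, 1+ weak,
2+ moderate, 3+ intense).  Percent positivity additionally maps onto the
conventional reporting bands 0 / 1-10 / 11-50 / 51-80 / >80.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed marker panel; every lesion must carry all seven.
MARKER_PANEL: tuple[str, ...] = ("UPK", "GATA3", "CK5", "CK14", "CK18", "CK20", "CD44")

#: Basal-differentiation markers (urothelial basal layer).
BASAL_MARKERS: tuple[str, ...] = ("CK5", "CK14", "CD44")

#: Luminal/umbrella-cell differentiation markers.
LUMINAL_MARKERS: tuple[str, ...] = ("UPK", "CK20", "CK18")

#: Reporting bands for percent positivity, upper endpoints inclusive.
POSITIVITY_BANDS: tuple[str, ...] = ("0", "1-10", "11-50", "51-80", ">80")


class LesionSite(str, enum.Enum):
    """Anatomic site of a scored lesion."""

    PRIMARY = "primary"
    NODE_RIGHT = "node_right"
    NODE_LEFT = "node_left"


class ValidationError(ValueError):
    """Raised when records violate the scoring invariants.

    ``errors`` lists every offending record/field, so a caller sees all
    problems at once rather than fail-fast on the first.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def positivity_band(percent: float) -> str:
    """Map a percent positivity onto its reporting band.

    Bands are ``0``, ``1-10``, ``11-50``, ``51-80`` and ``>80``, each
    inclusive of its upper endpoint (so 10 -> "1-10" but 10.5 -> "11-50";
    real-valued percents are allowed).

    Raises
    ------
    ValueError
        If ``percent`` is outside [0, 100].
    """
    if not 0 <= percent <= 100:
        raise ValueError(f"percent positivity {percent!r} outside [0, 100]")
    if percent == 0:
        return "0"
    if percent <= 10:
        return "1-10"
    if percent <= 50:
        return "11-50"
    if percent <= 80:
        return "51-80"
    return ">80"


@dataclass(frozen=True)
class MarkerScore:
    """One marker's semiquantitative score on one lesion."""

    percent: float
    intensity: int

    @property
    def band(self) -> str:
        return positivity_band(self.percent)


@dataclass
class IHCLesionRecord:
    """Seven-marker semiquantitative score sheet for one lesion.

    Invariants (enforced by :meth:`validate`): all panel markers present,
    percent in [0, 100], intensity in {0,1,2,3}, and intensity 0 iff
    percent 0 (no staining means no positive cells).
    """

    patient_id: str
    lesion_site: LesionSite
    scores: dict[str, MarkerScore]

    def validate(self) -> None:
        errors = self._errors()
        if errors:
            raise ValidationError(errors)

    def _errors(self) -> list[str]:
        tag = f"{self.patient_id}/{self.lesion_site.value}"
        errors: list[str] = []
        missing = [m for m in MARKER_PANEL if m not in self.scores]
        if missing:
            errors.append(f"{tag}: missing markers {missing}")
        extra = [m for m in self.scores if m not in MARKER_PANEL]
        if extra:
            errors.append(f"{tag}: unknown markers {extra}")
        for marker in MARKER_PANEL:
            score = self.scores.get(marker)
            if score is None:
                continue
            if not 0 <= score.percent <= 100:
                errors.append(
                    f"{tag}/{marker}: percent {score.percent} outside [0, 100]"
                )
            if score.intensity not in (0, 1, 2, 3):
                errors.append(
                    f"{tag}/{marker}: intensity {score.intensity} not in 0..3"
                )
            elif 0 <= score.percent <= 100 and (
                (score.intensity == 0) != (score.percent == 0)
            ):
                errors.append(
                    f"{tag}/{marker}: intensity {score.intensity} inconsistent "
                    f"with percent {score.percent} (intensity 0 iff percent 0)"
                )
        return errors

    def percent(self, marker: str) -> float:
        return self.scores[marker].percent


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates and survival endpoints.

    Times are months from cystectomy; ``pfs_*`` is progression-free survival
    (progression event or right-censor), ``os_*`` overall survival (death or
    right-censor).  ``pfs_time <= os_time`` must hold: a patient cannot be at
    risk of progression after death or after the last contact.
    """

    patient_id: str
    age_years: float
    sex: str  # "M" / "F"
    pt_stage: str  # "T2" / "T3" / "T4"
    nodal_pattern: str  # "unilateral" / "bilateral"
    treatment: str
    pfs_time: float
    pfs_event: bool
    os_time: float
    os_event: bool

    def validate(self) -> None:
        errors: list[str] = []
        if self.pt_stage not in ("T2", "T3", "T4"):
            errors.append(f"{self.patient_id}: pT stage {self.pt_stage!r} unknown")
        if self.nodal_pattern not in ("unilateral", "bilateral"):
            errors.append(
                f"{self.patient_id}: nodal pattern {self.nodal_pattern!r} unknown"
            )
        if self.pfs_time < 0 or self.os_time < 0:
            errors.append(f"{self.patient_id}: negative survival time")
        if self.pfs_time > self.os_time:
            errors.append(
                f"{self.patient_id}: pfs_time {self.pfs_time} > os_time {self.os_time}"
            )
        if errors:
            raise ValidationError(errors)


@dataclass
class CohortMatrix:
    """Patients x markers matrix of percent positivity for one lesion site."""

    values: np.ndarray  # shape (n_patients, n_markers)
    patient_ids: list[str]
    markers: list[str] = field(default_factory=lambda: list(MARKER_PANEL))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.markers)):
            raise ValidationError(
                [
                    f"matrix shape {self.values.shape} does not match "
                    f"{len(self.patient_ids)} patients x {len(self.markers)} markers"
                ]
            )
        if np.isnan(self.values).any():
            raise ValidationError(["matrix contains missing cells"])

    @classmethod
    def from_records(
        cls,
        records: list[IHCLesionRecord],
        site: LesionSite = LesionSite.PRIMARY,
    ) -> "CohortMatrix":
        """Assemble the matrix for one lesion site from validated records."""
        selected = [r for r in records if r.lesion_site == site]
        if not selected:
            raise ValidationError([f"no lesions at site {site.value}"])
        ids = [r.patient_id for r in selected]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError([f"duplicate lesions at {site.value}: {dupes}"])
        values = np.array(
            [[r.percent(m) for m in MARKER_PANEL] for r in selected], dtype=float
        )
        return cls(values=values, patient_ids=ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.markers)

    def marker_values(self, marker: str) -> np.ndarray:
        return self.values[:, self.markers.index(marker)]

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def intensity_from_percent(percent: float) -> int:
    """Deterministic ordinal intensity derived from percent positivity.

    0 -> 0; (0, 33] -> 1+; (33, 66] -> 2+; >66 -> 3+.  Intensity is never
    used quantitatively downstream, so a monotone rule keeps simulated and
    transcribed records consistent with the intensity-0-iff-percent-0
    invariant.
    """
    if percent == 0:
        return 0
    if percent <= 33:
        return 1
    if percent <= 66:
        return 2
    return 3


def marker_positivity_summary(
    cohort: CohortMatrix, cutoff: float = 1.0
) -> dict[str, float]:
    """Per-marker positivity rates (%) at an expression cutoff.

    A patient counts as positive for a marker when its percent positivity is
    >= ``cutoff`` (default 1%: any staining).  Rates are percentages of all
    patients, rounded to 2 decimals.  The returned mapping also carries the
    aggregate ``basal_panel`` (mean of CK5/CK14/CD44 rates) and
    ``luminal_panel`` (mean of UPK/CK20/CK18 rates) entries.

    Raises
    ------
    ValidationError
        If the cohort is empty.
    """
    if cohort.n_patients == 0:
        raise ValidationError(["empty cohort"])
    rates: dict[str, float] = {}
    for marker in cohort.markers:
        positive = int(np.sum(cohort.marker_values(marker) >= cutoff))
        rates[marker] = round(100.0 * positive / cohort.n_patients, 2)
    rates["basal_panel"] = round(
        float(np.mean([rates[m] for m in BASAL_MARKERS])), 2
    )
    rates["luminal_panel"] = round(
        float(np.mean([rates[m] for m in LUMINAL_MARKERS])), 2
    )
    return rates
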