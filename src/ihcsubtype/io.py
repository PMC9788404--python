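"""CSV reading/writing for IHC score sheets and clinical tables.

Dialects
--------
* long IHC CSV: one row per (patient, lesion_site, marker) with columns
  ``patient_id, lesion_site, marker, percent_positive, intensity``;
* clinical CSV: one row per patient, columns matching
  :class:`~ihcsubtype.datamodel.ClinicalRecord`;
* wide matrix CSV: markers as rows, patients as columns (the orientation of
  a heatmap with a top dendrogram over samples).

All files are UTF-8, comma-separated, with a header row; lines starting with
``#`` are treated as provenance comments and skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .datamodel import (
    MARKER_PANEL,
    ClinicalRecord,
    CohortMatrix,
    IHCLesionRecord,
    LesionSite,
    MarkerScore,
    ValidationError,
)

logger = logging.getLogger(__name__)

IHC_COLUMNS = ["patient_id", "lesion_site", "marker", "percent_positive", "intensity"]
CLINICAL_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "pt_stage",
    "nodal_pattern",
    "treatment",
    "pfs_time",
    "pfs_event",
    "os_time",
    "os_event",
]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError([f"{path.name}: missing columns {missing}"])
    return df


def read_ihc_csv(path: str | Path) -> list[IHCLesionRecord]:
    """Read and validate a long-form IHC CSV into lesion records."""
    df = _read_csv(path, IHC_COLUMNS)
    errors: list[str] = []
    for col in ("percent_positive", "intensity"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        for idx in df.index[bad]:
            errors.append(f"row {idx}, column {col}: cannot parse {df.at[idx, col]!r}")
    if errors:
        raise ValidationError(errors)
    df["percent_positive"] = pd.to_numeric(df["percent_positive"])
    df["intensity"] = pd.to_numeric(df["intensity"]).astype(int)

    records: list[IHCLesionRecord] = []
    for (pid, site), group in df.groupby(["patient_id", "lesion_site"], sort=True):
        try:
            lesion_site = LesionSite(site)
        except ValueError:
            errors.append(f"{pid}: unknown lesion site {site!r}")
            continue
        scores = {
            row.marker: MarkerScore(float(row.percent_positive), int(row.intensity))
            for row in group.itertuples()
        }
        record = IHCLesionRecord(str(pid), lesion_site, scores)
        errors.extend(record._errors())
        records.append(record)
    if errors:
        raise ValidationError(errors)
    return records


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    """Read and validate a clinical CSV."""
    df = _read_csv(path, CLINICAL_COLUMNS)
    records = []
    for row in df.itertuples():
        record = ClinicalRecord(
            patient_id=str(row.patient_id),
            age_years=float(row.age_years),
            sex=str(row.sex),
            pt_stage=str(row.pt_stage),
            nodal_pattern=str(row.nodal_pattern),
            treatment=str(row.treatment),
            pfs_time=float(row.pfs_time),
            pfs_event=bool(row.pfs_event),
            os_time=float(row.os_time),
            os_event=bool(row.os_event),
        )
        record.validate()
        records.append(record)
    return records


def read_cohort(
    ihc_path: str | Path, clinical_path: str | Path
) -> tuple[list[IHCLesionRecord], list[ClinicalRecord]]:
    """Read IHC and clinical tables together.

    Patients scored in the IHC table but absent from the clinical table are
    reported via a logging warning — never silently dropped (they remain in
    the returned records).
    """
    ihc = read_ihc_csv(ihc_path)
    clinical = read_clinical_csv(clinical_path)
    clinical_ids = {c.patient_id for c in clinical}
    orphans = sorted({r.patient_id for r in ihc} - clinical_ids)
    if orphans:
        logger.warning(
            "IHC table has %d patients without a clinical row: %s",
            len(orphans),
            orphans,
        )
    return ihc, clinical


def _provenance_header(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {key}: {value}\n" for key, value in sorted(metadata.items()))


def write_ihc_csv(
    records: list[IHCLesionRecord], path: str | Path, metadata: dict | None = None
) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "lesion_site": r.lesion_site.value,
            "marker": marker,
            "percent_positive": r.scores[marker].percent,
            "intensity": r.scores[marker].intensity,
        }
        for r in records
        for marker in MARKER_PANEL
    ]
    df = pd.DataFrame(rows, columns=IHC_COLUMNS)
    _write_with_header(df, path, metadata)


def write_clinical_csv(
    records: list[ClinicalRecord], path: str | Path, metadata: dict | None = None
) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=CLINICAL_COLUMNS)
    _write_with_header(df, path, metadata)


def write_wide_matrix(
    cohort: CohortMatrix, path: str | Path, metadata: dict | None = None
) -> None:
    """Write the clustering matrix with markers as rows, patients as columns."""
    df = cohort.to_frame().T
    df.index.name = "marker"
    _write_with_header(df.reset_index(), path, metadata)


def read_wide_matrix(path: str | Path) -> CohortMatrix:
    df = _read_csv(path, ["marker"]).set_index("marker")
    return CohortMatrix(
        values=df.to_numpy(dtype=float).T,
        patient_ids=[str(c) for c in df.columns],
        markers=[str(m) for m in df.index],
    )


def _write_with_header(df: pd.DataFrame, path: str | Path, metadata: dict | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_header(metadata))
        df.to_csv(fh, index=False)
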