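"""Bundled 38-patient reference cohort.

A deterministic, fully synthetic reconstruction of the published summary
counts of an institutional MIUC cohort (n = 38): per-patient marker percents
are representative values chosen so that the two-marker classifier at the
20% cutoff reproduces the reported subtype split (11 luminal / 10 basal /
16 mixed / 1 unclassified), the reported per-marker positivity rates
(GATA3 36/38, CK18 35/38, CK5 34/38, uroplakin 10/38), the
primary-vs-nodal cross-classification, and the bilateral nodal marginals
(8 luminal / 7 mixed per side).  Per-patient raw data were never published;
no record here corresponds to a real patient.

A quirk inherited from the published counts: the primary-vs-metastasis
cross-classification covers all 38 primaries (row totals 11/10/16/1) even
though only 23 patients had unilateral nodal disease — the published
analysis pooled every primary against a single nodal call.  The cohort
therefore designates one nodal lesion per patient (the only node for
unilateral patients, the right node for bilateral ones); cross-classifying
primaries against the designated nodes reproduces the printed stability
rates (luminal 90.91%, basal 60%, mixed 75%).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import SUBTYPES
from .datamodel import (
    MARKER_PANEL,
    ClinicalRecord,
    IHCLesionRecord,
    LesionSite,
    MarkerScore,
    intensity_from_percent,
)

# primary-lesion marker templates per subtype (percent positivity)
_PRIMARY_TEMPLATE = {
    "luminal": {"UPK": 0, "GATA3": 80, "CK5": 0, "CK14": 0, "CK18": 70, "CK20": 60, "CD44": 0},
    "basal": {"UPK": 0, "GATA3": 80, "CK5": 80, "CK14": 60, "CK18": 5, "CK20": 0, "CD44": 60},
    "mixed": {"UPK": 0, "GATA3": 80, "CK5": 60, "CK14": 0, "CK18": 70, "CK20": 0, "CD44": 0},
    "unclassified": {"UPK": 0, "GATA3": 80, "CK5": 0, "CK14": 0, "CK18": 0, "CK20": 60, "CD44": 0},
}

# nodal-lesion marker templates per metastasis call
_NODE_TEMPLATE = {
    "luminal": {"UPK": 60, "GATA3": 80, "CK5": 5, "CK14": 0, "CK18": 70, "CK20": 60, "CD44": 0},
    "basal": {"UPK": 0, "GATA3": 80, "CK5": 80, "CK14": 60, "CK18": 5, "CK20": 0, "CD44": 60},
    "mixed": {"UPK": 0, "GATA3": 80, "CK5": 60, "CK14": 5, "CK18": 70, "CK20": 5, "CD44": 0},
}

# patient layout: (primary subtype, designated nodal call, bilateral?)
_LAYOUT: list[tuple[str, str, bool]] = (
    # luminal primaries: 10 concordant (8 bilateral), 1 -> basal node
    [("luminal", "luminal", True)] * 8
    + [("luminal", "luminal", False)] * 2
    + [("luminal", "basal", False)]
    # basal primaries: 6 stay basal, 3 -> mixed, 1 -> luminal
    + [("basal", "basal", False)] * 6
    + [("basal", "mixed", False)] * 3
    + [("basal", "luminal", False)]
    # mixed primaries: 12 stay mixed (7 bilateral), 3 -> luminal, 1 -> basal
    + [("mixed", "mixed", True)] * 7
    + [("mixed", "mixed", False)] * 5
    + [("mixed", "luminal", False)] * 3
    + [("mixed", "basal", False)]
    # the single reject-pattern primary -> mixed node
    + [("unclassified", "mixed", False)]
)


# treatments of patients 31-38 (30 had cystectomy alone)
_LATE_TREATMENTS = (
    ["cystectomy+CT"] * 4
    + ["cystectomy+IT"] * 2
    + ["cystectomy+CT+IT", "cystectomy+RT"]
)


@dataclass
class ReferenceCohort:
    """The reconstructed cohort plus the summary values it must reproduce."""

    ihc_records: list[IHCLesionRecord]
    clinical_records: list[ClinicalRecord]
    expected: dict


def _lesion(pid: str, site: LesionSite, percents: dict[str, float]) -> IHCLesionRecord:
    scores = {
        m: MarkerScore(float(percents[m]), intensity_from_percent(percents[m]))
        for m in MARKER_PANEL
    }
    return IHCLesionRecord(pid, site, scores)


def _primary_percents(index: int, subtype: str) -> dict[str, float]:
    """Subtype template plus per-patient overrides matching the printed
    per-marker positivity counts (at the any-staining 1% cutoff)."""
    p = dict(_PRIMARY_TEMPLATE[subtype])
    pid_no = index + 1  # 1-based patient number
    if subtype == "luminal":
        if pid_no <= 10:
            p["UPK"] = 60  # uroplakin positive in 10/38
        if pid_no <= 8:
            p["CK5"] = 5  # faint CK5 staining in 8 luminal patients
    if subtype == "basal" and pid_no in (12, 13):
        p["GATA3"] = 0  # the two GATA3-negative patients
        p["CK18"] = 0  # CK18 silent in 3/38 (here plus the reject patient)
    if subtype == "mixed":
        if 22 <= pid_no <= 27:
            p["CK20"] = 5  # faint CK20 in 6 mixed patients
        if 22 <= pid_no <= 34:
            p["CK14"] = 5  # CK14 positive in 23/38 overall
        if 22 <= pid_no <= 32:
            p["CD44"] = 5  # CD44 positive in 21/38 overall
    return p


def _expected() -> dict:
    counts = pd.DataFrame(
        0,
        index=pd.Index(SUBTYPES, name="primary"),
        columns=pd.Index(SUBTYPES, name="metastasis"),
    )
    for primary, met, _ in _LAYOUT:
        counts.loc[primary, met] += 1
    return {
        "subtype_counts": {"luminal": 11, "basal": 10, "mixed": 16, "unclassified": 1},
        "subtype_percent": {
            "luminal": 28.95,
            "basal": 26.32,
            "mixed": 42.11,
            "unclassified": 2.63,
        },
        "pooled_concordance_counts": counts,
        "row_stability": {"luminal": 90.91, "basal": 60.0, "mixed": 75.0},
        "bilateral_marginal_counts": {"luminal": 8, "mixed": 7},
        "bilateral_marginal_percent": {"luminal": 53.33, "mixed": 46.67},
        "nodal_pattern_counts": {"unilateral": 23, "bilateral": 15},
        "nodal_pattern_percent": {"unilateral": 60.53, "bilateral": 39.47},
        "marker_positivity": {"GATA3": 94.74, "CK18": 92.11, "CK5": 89.47, "UPK": 26.32},
    }


def reference_cohort() -> ReferenceCohort:
    """Build the deterministic 38-patient reference cohort."""
    ihc: list[IHCLesionRecord] = []
    clinical: list[ClinicalRecord] = []

    unilateral_ids = [i for i, (_, _, bilateral) in enumerate(_LAYOUT) if not bilateral]
    right_unilateral = set(unilateral_ids[:11])  # 11 right-only, 12 left-only

    for i, (primary, met, bilateral) in enumerate(_LAYOUT):
        pid = f"P{i + 1:02d}"
        ihc.append(_lesion(pid, LesionSite.PRIMARY, _primary_percents(i, primary)))
        if bilateral:
            # designated node = right; contralateral carries the same call
            ihc.append(_lesion(pid, LesionSite.NODE_RIGHT, _NODE_TEMPLATE[met]))
            ihc.append(_lesion(pid, LesionSite.NODE_LEFT, _NODE_TEMPLATE[met]))
        else:
            site = LesionSite.NODE_RIGHT if i in right_unilateral else LesionSite.NODE_LEFT
            ihc.append(_lesion(pid, site, _NODE_TEMPLATE[met]))

        os_event = i < 23  # 23 deaths (printed clinical table)
        os_time = float(6 + 2 * i) if os_event else float(30 + 2 * (i - 23))
        pfs_event = i < 13  # 13 progressions
        pfs_time = round(os_time / 2, 1) if pfs_event else os_time
        clinical.append(
            ClinicalRecord(
                patient_id=pid,
                age_years=float(60 + (i % 16)),
                sex="M" if i < 33 else "F",
                pt_stage="T2" if i < 4 else ("T3" if i < 23 else "T4"),
                nodal_pattern="bilateral" if bilateral else "unilateral",
                treatment="cystectomy" if i < 30 else _LATE_TREATMENTS[i - 30],
                pfs_time=pfs_time,
                pfs_event=pfs_event,
                os_time=os_time,
                os_event=os_event,
            )
        )

    for record in ihc:
        record.validate()
    for record in clinical:
        record.validate()
    return ReferenceCohort(ihc_records=ihc, clinical_records=clinical, expected=_expected())


def designated_node_records(records: list[IHCLesionRecord]) -> list[IHCLesionRecord]:
    """One nodal lesion per patient: the right node when both sides exist.

    This is the designated nodal call used by the pooled primary-vs-node
    cross-classification (see module docstring).
    """
    by_patient: dict[str, dict[LesionSite, IHCLesionRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, {})[r.lesion_site] = r
    designated = []
    for pid in sorted(by_patient):
        sites = by_patient[pid]
        node = sites.get(LesionSite.NODE_RIGHT) or sites.get(LesionSite.NODE_LEFT)
        if node is not None:
            designated.append(node)
    return designated
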