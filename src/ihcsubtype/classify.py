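"""Two-marker immunophenotype classification of urothelial carcinoma lesions.

The simplified classifier reads only CK20 and CK18 at a single expression
cutoff (default 20% of positive tumor cells):

==============  ==============  =============
CK20 >= cutoff  CK18 >= cutoff  immunophenotype
==============  ==============  =============
yes             yes             luminal
no              yes             mixed
no              no              basal
yes             no              unclassified
==============  ==============  =============

The CK20+/CK18- cell has no biological label in the luminal/basal/mixed
scheme, so the classifier carries an explicit reject state rather than
forcing a call.  CK5 and GATA3 status at the same cutoff annotate the call
(``CK5+/GATA3-`` etc.) but never change it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import IHCLesionRecord, LesionSite, ValidationError

#: Major immunophenotypes, in reporting order.
SUBTYPES: tuple[str, ...] = ("luminal", "basal", "mixed", "unclassified")


@dataclass(frozen=True)
class SubtypeCall:
    """One lesion's immunophenotype call."""

    patient_id: str
    lesion_site: LesionSite
    major: str
    sub: str
    cutoff_used: float


def _major_call(ck20: float, ck18: float, cutoff: float) -> str:
    if ck18 >= cutoff:
        return "luminal" if ck20 >= cutoff else "mixed"
    return "unclassified" if ck20 >= cutoff else "basal"


def _sub_label(ck5: float, gata3: float, cutoff: float) -> str:
    ck5_sign = "+" if ck5 >= cutoff else "-"
    gata_sign = "+" if gata3 >= cutoff else "-"
    return f"CK5{ck5_sign}/GATA3{gata_sign}"


def classify_two_marker(record: IHCLesionRecord, cutoff: float = 20.0) -> SubtypeCall:
    """Classify one lesion from its CK20/CK18 scores at the given cutoff.

    A marker counts as expressed when its percent positivity is >= cutoff
    (a lesion at exactly the cutoff is positive).
    """
    for marker in ("CK20", "CK18", "CK5", "GATA3"):
        if marker not in record.scores:
            raise ValidationError(
                [f"{record.patient_id}/{record.lesion_site.value}: missing {marker}"]
            )
    ck20 = record.percent("CK20")
    ck18 = record.percent("CK18")
    return SubtypeCall(
        patient_id=record.patient_id,
        lesion_site=record.lesion_site,
        major=_major_call(ck20, ck18, cutoff),
        sub=_sub_label(record.percent("CK5"), record.percent("GATA3"), cutoff),
        cutoff_used=cutoff,
    )


def classify_cohort(
    records: list[IHCLesionRecord],
    cutoff: float = 20.0,
    site: LesionSite = LesionSite.PRIMARY,
) -> tuple[list[SubtypeCall], pd.DataFrame]:
    """Classify every lesion at one site and tabulate subtype shares.

    Returns the per-lesion calls plus a proportion table (counts and
    percentages to 2 decimals over all patients at that site; unclassified
    lesions stay in the denominator).

    Raises
    ------
    ValidationError
        If no lesion exists at ``site`` or a patient has duplicates there.
    """
    selected = [r for r in records if r.lesion_site == site]
    if not selected:
        raise ValidationError([f"no lesions at site {site.value}"])
    ids = [r.patient_id for r in selected]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError([f"duplicate {site.value} lesions: {dupes}"])
    calls = [classify_two_marker(r, cutoff) for r in selected]
    return calls, proportion_table(calls)


def proportion_table(calls: list[SubtypeCall]) -> pd.DataFrame:
    """Counts and percentages (2 decimals) per immunophenotype."""
    n = len(calls)
    counts = {s: sum(1 for c in calls if c.major == s) for s in SUBTYPES}
    return pd.DataFrame(
        {
            "count": [counts[s] for s in SUBTYPES],
            "percent": [round(100.0 * counts[s] / n, 2) for s in SUBTYPES],
        },
        index=pd.Index(SUBTYPES, name="subtype"),
    )


def cutoff_sensitivity(
    records: list[IHCLesionRecord],
    cutoffs: list[float],
    site: LesionSite = LesionSite.PRIMARY,
) -> pd.DataFrame:
    """Subtype shares as a function of the expression cutoff.

    One row per cutoff, columns = subtype percentage shares; supports the
    cutoff-sweep plot where a vertical line marks the working cutoff.
    """
    if not cutoffs:
        raise ValueError("at least one cutoff required")
    bad = [c for c in cutoffs if not 0 < c < 100]
    if bad:
        raise ValueError(f"cutoffs outside (0, 100): {bad}")
    rows = {}
    for cutoff in cutoffs:
        _, table = classify_cohort(records, cutoff=cutoff, site=site)
        rows[cutoff] = table["percent"]
    out = pd.DataFrame(rows).T
    out.index.name = "cutoff"
    return out


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "lesion_site": c.lesion_site.value,
                "major": c.major,
                "sub": c.sub,
                "cutoff_used": c.cutoff_used,
            }
            for c in calls
        ]
    )
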