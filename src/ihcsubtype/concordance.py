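"""Primary-tumor vs lymph-node-metastasis immunophenotype concordance.

Cross-classifies paired subtype calls into a K x K table (K = 4, the three
immunophenotypes plus the explicit unclassified state), computes per-row
stability rates (the fraction of primaries whose metastasis keeps the same
call), and estimates the row-stochastic subtype transition matrix with
percentile-bootstrap confidence intervals over patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import SUBTYPES, SubtypeCall
from .datamodel import ValidationError


@dataclass
class ConcordanceTable:
    """K x K cross-classification of primary (rows) vs metastasis (columns)."""

    counts: pd.DataFrame  # integer counts, index/columns = SUBTYPES

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError(["negative concordance counts"])

    @property
    def n_patients(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_stability(self) -> pd.Series:
        """Per-primary-subtype stability rate (%), 2 decimals; NaN for empty rows."""
        diag = pd.Series(np.diag(self.counts), index=self.counts.index, dtype=float)
        row_sums = self.counts.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = 100.0 * diag / row_sums.replace(0, np.nan)
        return rates.round(2)

    @property
    def overall_concordance(self) -> float:
        """Percentage of all pairs on the diagonal, 2 decimals."""
        return round(100.0 * float(np.trace(self.counts)) / self.n_patients, 2)


def _paired(
    primary_calls: list[SubtypeCall], met_calls: list[SubtypeCall]
) -> list[tuple[str, str, str]]:
    primaries = {c.patient_id: c for c in primary_calls}
    mets = {c.patient_id: c for c in met_calls}
    unmatched = sorted(set(primaries) ^ set(mets))
    if unmatched:
        raise ValidationError([f"unpaired patients: {unmatched}"])
    return [(pid, primaries[pid].major, mets[pid].major) for pid in sorted(primaries)]


def unilateral_concordance(
    primary_calls: list[SubtypeCall], met_calls: list[SubtypeCall]
) -> ConcordanceTable:
    """Cross-classify each patient's primary call against one nodal call.

    Every patient must appear exactly once in both lists; unmatched IDs are
    reported by ID in the raised error.
    """
    pairs = _paired(primary_calls, met_calls)
    counts = pd.DataFrame(
        0, index=pd.Index(SUBTYPES, name="primary"), columns=pd.Index(SUBTYPES, name="metastasis")
    )
    for _, p, m in pairs:
        counts.loc[p, m] += 1
    return ConcordanceTable(counts)


@dataclass
class BilateralSummary:
    """Per-patient (primary, right node, left node) triples plus marginals."""

    triples: pd.DataFrame  # columns patient_id, primary, right, left
    right_marginal: pd.DataFrame  # count + percent per subtype
    left_marginal: pd.DataFrame
    n_fully_concordant: int


def _marginal(labels: list[str]) -> pd.DataFrame:
    n = len(labels)
    counts = {s: labels.count(s) for s in SUBTYPES}
    return pd.DataFrame(
        {
            "count": [counts[s] for s in SUBTYPES],
            "percent": [round(100.0 * counts[s] / n, 2) for s in SUBTYPES],
        },
        index=pd.Index(SUBTYPES, name="subtype"),
    )


def bilateral_paired_summary(
    primary_calls: list[SubtypeCall],
    right_calls: list[SubtypeCall],
    left_calls: list[SubtypeCall],
) -> BilateralSummary:
    """Summarize bilateral (paired) nodal metastases against the primary.

    Each patient needs a primary, a right-node and a left-node call; a
    missing side is an error naming the patients.
    """
    by_id = lambda calls: {c.patient_id: c for c in calls}  # noqa: E731
    primaries, rights, lefts = by_id(primary_calls), by_id(right_calls), by_id(left_calls)
    missing = sorted(
        (set(primaries) | set(rights) | set(lefts))
        - (set(primaries) & set(rights) & set(lefts))
    )
    if missing:
        raise ValidationError([f"patients missing a lesion call: {missing}"])
    rows = [
        {
            "patient_id": pid,
            "primary": primaries[pid].major,
            "right": rights[pid].major,
            "left": lefts[pid].major,
        }
        for pid in sorted(primaries)
    ]
    triples = pd.DataFrame(rows)
    concordant = int(
        ((triples["primary"] == triples["right"]) & (triples["primary"] == triples["left"])).sum()
    )
    return BilateralSummary(
        triples=triples,
        right_marginal=_marginal(list(triples["right"])),
        left_marginal=_marginal(list(triples["left"])),
        n_fully_concordant=concordant,
    )


@dataclass
class TransitionEstimate:
    """Row-normalized transition matrix with percentile bootstrap CIs."""

    matrix: pd.DataFrame  # row-stochastic where row sums > 0, NaN otherwise
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n_boot: int


def transition_matrix_estimate(
    table: ConcordanceTable, n_boot: int = 2000, seed: int = 0
) -> TransitionEstimate:
    """Estimate P(metastasis subtype | primary subtype) from a concordance table.

    The point estimate row-normalizes the counts.  Confidence intervals are
    95% percentile-bootstrap over patients: the observed pairs are resampled
    with replacement ``n_boot`` times and each cell's conditional frequency
    recomputed.  Rows with zero observations stay NaN.
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.sum() == 0:
        raise ValidationError(["empty concordance table"])
    k = counts.shape[0]
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        point = np.where(row_sums > 0, counts / row_sums, np.nan)

    # reconstruct the pair list (row index, col index) and bootstrap patients
    pairs = np.repeat(
        np.arange(k * k), counts.astype(int).ravel()
    )  # each pair encoded as row*k + col
    n = len(pairs)
    rng = np.random.default_rng(seed)
    boots = np.full((n_boot, k, k), np.nan)
    for b in range(n_boot):
        resampled = pairs[rng.integers(0, n, n)]
        boot_counts = np.bincount(resampled, minlength=k * k).reshape(k, k).astype(float)
        boot_rows = boot_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            boots[b] = np.where(boot_rows > 0, boot_counts / boot_rows, np.nan)

    with np.errstate(invalid="ignore"):
        low = np.nanpercentile(boots, 2.5, axis=0)
        high = np.nanpercentile(boots, 97.5, axis=0)
    idx = table.counts.index
    cols = table.counts.columns
    as_df = lambda a: pd.DataFrame(a, index=idx, columns=cols)  # noqa: E731
    return TransitionEstimate(
        matrix=as_df(point), ci_low=as_df(low), ci_high=as_df(high), n_boot=n_boot
    )
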