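import numpy as np
import pytest

from ihcsubtype.classify import SUBTYPES, SubtypeCall, classify_two_marker
from ihcsubtype.concordance import (
    bilateral_paired_summary,
    transition_matrix_estimate,
    unilateral_concordance,
)
from ihcsubtype.datamodel import LesionSite, ValidationError
from ihcsubtype.reference import designated_node_records
from ihcsubtype.synthetic import default_transition_matrix


def call(pid, major, site=LesionSite.PRIMARY):
    return SubtypeCall(pid, site, major, "CK5+/GATA3+", 20.0)


@pytest.fixture(scope="module")
def reference_tables(cohort):
    primaries = {
        r.patient_id: classify_two_marker(r)
        for r in cohort.ihc_records
        if r.lesion_site == LesionSite.PRIMARY
    }
    designated = [classify_two_marker(r) for r in designated_node_records(cohort.ihc_records)]
    pooled = unilateral_concordance(
        [primaries[c.patient_id] for c in designated], designated
    )
    return pooled


class TestUnilateralConcordance:
    def test_reference_counts_and_stability(self, cohort, reference_tables):
        pooled = reference_tables
        expected_counts = cohort.expected["pooled_concordance_counts"]
        assert (pooled.counts.to_numpy() == expected_counts.to_numpy()).all()
        stability = pooled.row_stability
        for subtype, expected in cohort.expected["row_stability"].items():
            assert stability[subtype] == pytest.approx(expected)

    def test_row_sums_equal_primary_subtype_counts(self, cohort, reference_tables):
        row_sums = reference_tables.counts.sum(axis=1)
        for subtype, n in cohort.expected["subtype_counts"].items():
            assert row_sums[subtype] == n

    def test_identical_calls_give_identity_table(self):
        primaries = [call(f"P{i}", SUBTYPES[i % 4]) for i in range(8)]
        mets = [call(c.patient_id, c.major, LesionSite.NODE_RIGHT) for c in primaries]
        table = unilateral_concordance(primaries, mets)
        assert np.trace(table.counts) == 8
        assert table.overall_concordance == 100.0
        assert (table.row_stability.dropna() == 100.0).all()

    def test_unmatched_patients_listed(self):
        with pytest.raises(ValidationError, match="P9"):
            unilateral_concordance([call("P1", "luminal")], [call("P9", "basal")])

    def test_patient_order_invariance(self):
        primaries = [call(f"P{i}", SUBTYPES[i % 3]) for i in range(9)]
        mets = [call(f"P{i}", SUBTYPES[(i + 1) % 3]) for i in range(9)]
        a = unilateral_concordance(primaries, mets)
        b = unilateral_concordance(primaries[::-1], mets[::-1])
        assert (a.counts == b.counts).all().all()


class TestBilateralSummary:
    def test_reference_marginals(self, cohort):
        bilateral_ids = {
            c.patient_id for c in cohort.clinical_records if c.nodal_pattern == "bilateral"
        }
        assert len(bilateral_ids) == 15
        by_site = lambda site: [  # noqa: E731
            classify_two_marker(r)
            for r in cohort.ihc_records
            if r.lesion_site == site and r.patient_id in bilateral_ids
        ]
        summary = bilateral_paired_summary(
            [
                classify_two_marker(r)
                for r in cohort.ihc_records
                if r.lesion_site == LesionSite.PRIMARY and r.patient_id in bilateral_ids
            ],
            by_site(LesionSite.NODE_RIGHT),
            by_site(LesionSite.NODE_LEFT),
        )
        for side in (summary.right_marginal, summary.left_marginal):
            assert side.loc["luminal", "count"] == 8
            assert side.loc["mixed", "count"] == 7
            assert side.loc["luminal", "percent"] == pytest.approx(53.33)
            assert side.loc["mixed", "percent"] == pytest.approx(46.67)

    def test_identical_triples_fully_concordant(self):
        primaries = [call(f"P{i}", "mixed") for i in range(5)]
        right = [call(f"P{i}", "mixed", LesionSite.NODE_RIGHT) for i in range(5)]
        left = [call(f"P{i}", "mixed", LesionSite.NODE_LEFT) for i in range(5)]
        summary = bilateral_paired_summary(primaries, right, left)
        assert summary.n_fully_concordant == 5

    def test_missing_side_rejected(self):
        with pytest.raises(ValidationError, match="P1"):
            bilateral_paired_summary(
                [call("P1", "mixed")],
                [call("P1", "mixed", LesionSite.NODE_RIGHT)],
                [],
            )


class TestTransitionEstimate:
    def test_reference_luminal_row(self, reference_tables):
        estimate = transition_matrix_estimate(reference_tables, n_boot=200, seed=0)
        row = estimate.matrix.loc["luminal"]
        assert row["luminal"] == pytest.approx(10 / 11)
        assert row["basal"] == pytest.approx(1 / 11)
        assert row["mixed"] == 0.0
        assert row["unclassified"] == 0.0

    def test_identity_counts_give_identity_matrix_with_zero_ci_width(self):
        primaries = [call(f"P{i}", SUBTYPES[i % 4]) for i in range(16)]
        mets = [call(c.patient_id, c.major, LesionSite.NODE_RIGHT) for c in primaries]
        table = unilateral_concordance(primaries, mets)
        estimate = transition_matrix_estimate(table, n_boot=100, seed=1)
        assert np.allclose(estimate.matrix.to_numpy(), np.eye(4))
        width = (estimate.ci_high - estimate.ci_low).to_numpy()
        assert np.nanmax(width) == 0.0  # pure rows stay pure in every resample

    def test_empty_table_rejected(self, reference_tables):
        empty = reference_tables.counts * 0
        from ihcsubtype.concordance import ConcordanceTable

        with pytest.raises(ValidationError):
            transition_matrix_estimate(ConcordanceTable(empty))

    def test_bootstrap_ci_covers_generating_matrix(self):
        """Scaled-down coverage check: pairs drawn from the default transition
        matrix; the generating cell value should fall inside the 95% bootstrap
        CI for ~95% of estimable cells across replicates."""
        T = default_transition_matrix()
        mixture = np.array([11, 10, 16, 1]) / 38
        rng = np.random.default_rng(2024)
        inside = total = 0
        for _ in range(40):
            primaries, mets = [], []
            for i in range(200):
                p = SUBTYPES[rng.choice(4, p=mixture)]
                m = SUBTYPES[rng.choice(4, p=T.loc[p].to_numpy())]
                primaries.append(call(f"P{i}", p))
                mets.append(call(f"P{i}", m, LesionSite.NODE_RIGHT))
            table = unilateral_concordance(primaries, mets)
            est = transition_matrix_estimate(table, n_boot=300, seed=int(rng.integers(2**31)))
            for s in SUBTYPES:
                for t in SUBTYPES:
                    if np.isnan(est.matrix.loc[s, t]):
                        continue
                    total += 1
                    if est.ci_low.loc[s, t] <= T.loc[s, t] <= est.ci_high.loc[s, t]:
                        inside += 1
        assert inside / total >= 0.90

    def test_estimator_consistency_with_sample_size(self):
        """Cell-wise error of the estimated transition matrix shrinks from
        n = 200 to n = 2000 pairs drawn from the generating matrix."""
        T = default_transition_matrix()
        mixture = np.array([11, 10, 16, 1]) / 38
        errors = {}
        for n in (200, 2000):
            rng = np.random.default_rng(7)
            primaries, mets = [], []
            for i in range(n):
                p = SUBTYPES[rng.choice(4, p=mixture)]
                m = SUBTYPES[rng.choice(4, p=T.loc[p].to_numpy())]
                primaries.append(call(f"P{i}", p))
                mets.append(call(f"P{i}", m, LesionSite.NODE_RIGHT))
            table = unilateral_concordance(primaries, mets)
            est = transition_matrix_estimate(table, n_boot=10, seed=0)
            errors[n] = np.nanmax(np.abs(est.matrix.to_numpy() - T.to_numpy()))
        assert errors[2000] < errors[200]
        assert errors[2000] < 0.05
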