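import numpy as np
import pytest

from ihcsubtype.datamodel import CohortMatrix, LesionSite
from ihcsubtype.reference import reference_cohort


@pytest.fixture(scope="session")
def cohort():
    """The bundled 38-patient reference cohort."""
    return reference_cohort()


@pytest.fixture(scope="session")
def primary_matrix(cohort):
    return CohortMatrix.from_records(cohort.ihc_records, LesionSite.PRIMARY)


@pytest.fixture(scope="session")
def three_block_matrix():
    """Three mutually symmetric planted blocks of 6 patients.

    Each block expresses its own private marker pair (high Beta(8,2) draws)
    while every other marker is near-silent (Beta(1,20)); marker 7 is silent
    everywhere.  The symmetry leaves no preferred pairing of blocks, so only
    the three block nodes should be bootstrap-stable.
    """
    rng = np.random.default_rng(0)
    rows, ids, blocks = [], [], {}
    for b, hi in enumerate([(0, 1), (2, 3), (4, 5)]):
        members = []
        for k in range(6):
            row = 100 * rng.beta(1, 20, size=7)
            for m in hi:
                row[m] = 100 * rng.beta(8, 2)
            rows.append(row)
            pid = f"B{b}{k:02d}"
            ids.append(pid)
            members.append(pid)
        blocks[b] = members
    return CohortMatrix(np.array(rows), ids), blocks
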