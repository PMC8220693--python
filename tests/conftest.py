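import numpy as np
import pandas as pd
import pytest

from cfmdna.simulate import SimConfig, default_evidence_lists, simulate_cohort
from cfmdna.tables import AsvCountTable, StudyDesign


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed fixed)."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def evidence_lists():
    return default_evidence_lists()


@pytest.fixture
def small_table():
    """3 ASVs x 4 samples with simple hand-checkable counts."""
    return AsvCountTable(
        pd.DataFrame(
            {
                "s1": [5, 1, 0],
                "s2": [0, 2, 7],
                "s3": [3, 3, 3],
                "s4": [10, 0, 2],
            },
            index=["asv1", "asv2", "asv3"],
        )
    )


@pytest.fixture
def small_design():
    return StudyDesign(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "sample_type": ["plasma", "plasma", "plasma_denc", "plasma_denc"],
                "sequencing_run": ["r1"] * 4,
                "extraction_batch": ["A"] * 4,
                "extraction_day": ["A_d1", "A_d1", "A_d2", "A_d2"],
            }
        )
    )


def random_count_table(rng: np.random.Generator, n_asv=12, n_samp=6, lam=20.0) -> AsvCountTable:
    counts = rng.poisson(lam, size=(n_asv, n_samp))
    counts[0] += 1  # keep every sample non-empty
    return AsvCountTable(
        pd.DataFrame(
            counts,
            index=[f"a{i}" for i in range(n_asv)],
            columns=[f"s{j}" for j in range(n_samp)],
        )
    )
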