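import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mtfe import (
    QuantMatrix,
    SampleMetadata,
    SimulationConfig,
    align_fractions,
    compute_mtfe,
    generate_cohort,
)


@pytest.fixture
def tiny_matrix() -> QuantMatrix:
    values = np.array([[10.0, 11.0], [12.0, np.nan], [8.0, 9.5]])
    return QuantMatrix(["P1", "P2", "P3"], ["S1", "S2"], values, fraction="lysate")


@pytest.fixture
def tiny_meta() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2"],
                "subject_id": ["M1", "M2"],
                "genotype": ["WT", "WT"],
                "condition": ["Ctrl", "DEN"],
                "cohort": ["c1", "c1"],
                "pair_id": [None, None],
                "replicate": [0, 0],
            }
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    cfg = SimulationConfig(
        n_proteins=400,
        scenario_counts={i: 10 for i in range(2, 11)},
        n_replicates=5,
        missing_rate=0.02,
        seed=11,
    )
    mito, lysate, meta, truth = generate_cohort(cfg)
    return mito, lysate, meta, truth


@pytest.fixture(scope="session")
def small_cohort_mtfe(small_cohort):
    mito, lysate, meta, truth = small_cohort
    pair = align_fractions(mito, lysate, meta)
    return compute_mtfe(pair), pair, meta, truth
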