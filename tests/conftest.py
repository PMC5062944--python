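import random

import numpy as np
import pytest

from genoprivacy.simulate import GenotypeSimConfig, simulate_genotypes
from genoprivacy.variants import MISSING, GenotypeMatrix


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """4 samples x 3 sites, hand-checkable, with one missing entry and one
    degenerate (all-missing) site appended."""
    dosages = np.array(
        [
            [0, 1, MISSING],
            [2, 1, MISSING],
            [1, 0, MISSING],
            [1, MISSING, MISSING],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        samples=["case_1", "case_2", "ctrl_1", "ctrl_2"],
        sites=["s1", "s2", "s_allmiss"],
        dosages=dosages,
        labels=np.array(["case", "case", "control", "control"], dtype=object),
    )


@pytest.fixture
def cohort_311() -> GenotypeMatrix:
    """A 200+200 cohort over a reduced site panel (25 sites for speed), with
    missingness and planted effects."""
    cfg = GenotypeSimConfig(
        n_sites=25, n_assoc_sites=3, odds_ratio=2.0, missing_rate=0.02, seed=42
    )
    return simulate_genotypes(cfg)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20150301)
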