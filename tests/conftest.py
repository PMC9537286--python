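import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

import rgx


@pytest.fixture(scope="session")
def sphere_pair():
    """A 10 mm-radius sphere at 1 mm isotropic spacing (no texture/outliers)."""
    return rgx.generate_tumour_volume(
        0.0, 0.0, 20.0, (1.0, 1.0, 1.0), seed=0, include_outliers=False
    )


@pytest.fixture(scope="session")
def textured_pair():
    """An irregular, textured tumour with air/bone inclusions."""
    return rgx.generate_tumour_volume(0.4, 0.6, 18.0, (1.0, 1.0, 1.0), seed=3)


@pytest.fixture(scope="session")
def centroids():
    return rgx.make_centroids(200, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A fast cohort (18 + 12 patients, small tumours) for integration tests."""
    cfg = rgx.CohortConfig(
        n_discovery=18,
        n_validation=12,
        tumour_size_mm=13.0,
        spacing=(1.0, 1.0, 1.0),
        n_centroid_genes=120,
        n_extra_genes=160,
        seed=42,
    )
    return rgx.generate_cohort(cfg)
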