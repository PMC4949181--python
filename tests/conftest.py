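import numpy as np
import pandas as pd
import pytest

from refstab.datatypes import ANNOTATION_FIELDS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_grid():
    """4 genes x 6 samples Ct grid with distinct, fixed values."""
    rng = np.random.default_rng(7)
    genes = ["A", "B", "C", "D"]
    samples = [f"s{i}" for i in range(1, 7)]
    base = rng.normal(22.0, 2.0, size=(4, 1))
    noise = rng.normal(0.0, 0.5, size=(4, 6))
    return pd.DataFrame(base + noise, index=genes, columns=samples)


def make_annotations(samples, water=None):
    """Minimal complete annotation sheet for the given sample ids."""
    n = len(samples)
    water = water or ["well-watered" if i % 2 == 0 else "drought" for i in range(n)]
    return pd.DataFrame(
        {
            "genotype": ["IR64"] * n,
            "stage": ["seedling"] * n,
            "tissue": ["root"] * n,
            "water_status": water,
        },
        index=pd.Index(samples, name="sample"),
    )[list(ANNOTATION_FIELDS)]


@pytest.fixture
def annotations6():
    return make_annotations([f"s{i}" for i in range(1, 7)])
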