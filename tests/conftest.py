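import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_mask(rng: np.random.Generator, size: int = 90) -> np.ndarray:
    """A random binary mask: scattered pixels, boxes or disks on a grid."""
    mask = np.zeros((size, size), dtype=bool)
    kind = rng.integers(0, 3)
    if kind == 0:  # pixel scatter
        n = int(rng.integers(3, 60))
        rr = rng.integers(0, size, n)
        cc = rng.integers(0, size, n)
        mask[rr, cc] = True
    elif kind == 1:  # union of random axis-aligned boxes
        for _ in range(int(rng.integers(1, 4))):
            r0, c0 = rng.integers(0, size - 10, 2)
            h, w = rng.integers(2, 25, 2)
            mask[r0 : r0 + h, c0 : c0 + w] = True
    else:  # union of random disks
        rr, cc = np.mgrid[0:size, 0:size]
        for _ in range(int(rng.integers(1, 4))):
            r0, c0 = rng.integers(15, size - 15, 2)
            rad = int(rng.integers(3, 14))
            mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    if mask.sum() < 3:
        mask[size // 2, size // 2 : size // 2 + 3] = True
    return mask


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture
def small_table() -> pd.DataFrame:
    """Balanced 2-genotype x 2-treatment x 2-rep table with hand-set values."""
    rows = []
    values = {
        ("A", "control"): [10.0, 12.0],
        ("A", "deficient"): [7.0, 9.0],
        ("B", "control"): [14.0, 16.0],
        ("B", "deficient"): [9.0, 11.0],
    }
    for (geno, treat), vals in values.items():
        for rep, v in enumerate(vals, start=1):
            rows.append({"genotype": geno, "treatment": treat, "rep": rep, "y": v})
    return pd.DataFrame(rows)
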