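import numpy as np
import pytest

from threeoff2.dataset import CategoricalDataset


def make_dataset(columns: dict[str, list[int]]) -> CategoricalDataset:
    """Build a dataset from explicit integer-coded columns (test helper)."""
    names = list(columns)
    values = np.column_stack([np.asarray(columns[n], dtype=np.int64) for n in names])
    levels = values.max(axis=0) + 1
    return CategoricalDataset(values, names, levels)


def random_dataset(rng: np.random.Generator, n: int, v: int, r_max: int = 3) -> CategoricalDataset:
    """Dependent-ish random categorical data (mixture tilts, so MI is nonzero)."""
    base = rng.integers(0, 2, size=n)
    cols = {}
    for j in range(v):
        r = int(rng.integers(2, r_max + 1))
        noise = rng.integers(0, r, size=n)
        keep = rng.random(n) < rng.uniform(0.2, 0.8)
        cols[f"v{j}"] = np.where(keep, base % r, noise)
    return make_dataset(cols)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def xor_dataset():
    """Balanced x, y independent; z = XOR(x, y): I(x;y)=0, I(x;y|z)=ln 2."""
    x = [0, 0, 1, 1, 0, 0, 1, 1]
    y = [0, 1, 0, 1, 0, 1, 0, 1]
    z = [a ^ b for a, b in zip(x, y)]
    return make_dataset({"x": x, "y": y, "z": z})
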