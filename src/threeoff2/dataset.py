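"""Categorical observational data and joint-count tables.

All downstream information and complexity estimates are plug-in functionals of
joint counts over subsets of variables; this module owns the integer-coded data
matrix and the sparse contingency tables those estimates are built from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CategoricalDataset",
    "ContingencyTable",
    "DataFormatError",
    "MissingDataError",
    "load_table",
    "count_joint",
]


class DataFormatError(ValueError):
    """Raised for ragged or otherwise malformed input tables."""


class MissingDataError(ValueError):
    """Raised when the input contains empty cells; only complete cases are supported."""


@dataclass(frozen=True)
class CategoricalDataset:
    """N samples x V integer-coded categorical variables.

    Codes for variable ``v`` lie in ``[0, levels[v])``.  Levels count the
    *observed* distinct categories; theoretical categories never seen in the
    data do not exist as far as the estimators are concerned.
    """

    values: np.ndarray
    variable_names: list[str]
    levels: np.ndarray
    categories: list[list[str]] = field(default=None, repr=False)

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise DataFormatError("values must be a 2-D samples x variables matrix")
        if values.shape[0] < 1:
            raise DataFormatError("at least one sample is required")
        if values.shape[1] != len(self.variable_names):
            raise DataFormatError("variable_names length does not match columns")
        levels = np.asarray(self.levels, dtype=np.int64)
        if np.any(levels < 1):
            raise DataFormatError("every variable needs at least one observed level")
        if np.any(values < 0) or np.any(values >= levels[None, :]):
            raise DataFormatError("coded values out of the [0, r_v) range")
        object.__setattr__(self, "values", np.ascontiguousarray(values, dtype=np.int64))
        object.__setattr__(self, "levels", levels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    # N is the field name used throughout the scoring formulas
    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def index_of(self, name: str) -> int:
        return self.variable_names.index(name)

    def joint_codes(self, variables) -> tuple[np.ndarray, int]:
        """Mixed-radix encoding of the joint state of ``variables`` per sample.

        Returns the per-sample joint code and the total number of joint states
        (product of levels).  The empty subset maps every sample to state 0.
        """
        variables = list(variables)
        if not variables:
            return np.zeros(self.n_samples, dtype=np.int64), 1
        dims = self.levels[variables]
        codes = np.ravel_multi_index(
            tuple(self.values[:, v] for v in variables), tuple(int(d) for d in dims)
        )
        return codes.astype(np.int64), int(np.prod(dims))

    def to_frame(self) -> pd.DataFrame:
        """Decode back to a label DataFrame (labels if known, else codes)."""
        if self.categories is not None:
            cols = {
                name: [self.categories[j][c] for c in self.values[:, j]]
                for j, name in enumerate(self.variable_names)
            }
        else:
            cols = {name: self.values[:, j] for j, name in enumerate(self.variable_names)}
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class ContingencyTable:
    """Sparse joint counts over an ordered variable subset.

    Only observed joint states are stored; absent states have count zero.
    """

    variables: tuple[int, ...]
    counts: dict
    total: int

    def marginalize(self, variable: int) -> "ContingencyTable":
        """Sum out one variable; counts are conserved exactly."""
        if variable not in self.variables:
            raise KeyError(f"variable {variable} not in table")
        pos = self.variables.index(variable)
        kept = tuple(v for v in self.variables if v != variable)
        out: dict = {}
        for state, n in self.counts.items():
            reduced = state[:pos] + state[pos + 1 :]
            out[reduced] = out.get(reduced, 0) + n
        return ContingencyTable(kept, out, self.total)

    def count_vector(self) -> np.ndarray:
        return np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))


def load_table(path, delimiter: str = "\t", has_header: bool = True) -> CategoricalDataset:
    """Read a delimited text table of categorical observations.

    Values are treated as opaque string labels and integer-coded in
    lexicographic label order (deterministic across runs and column
    permutations).  Missing cells are rejected: the estimators assume complete
    cases.
    """
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if has_header else None,
            dtype=str,
            skip_blank_lines=False,
            keep_default_na=False,
            na_values=[""],
        )
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"malformed table: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError("empty input file") from exc
    if df.shape[0] < 1:
        raise DataFormatError("table has no data rows")
    if df.isna().any().any():
        raise MissingDataError("empty cells found; missing data is not supported")
    names = [str(c) for c in df.columns]
    if len(set(names)) != len(names):
        raise DataFormatError("duplicate column names")
    n, v = df.shape
    if n < 10:
        warnings.warn(f"only {n} samples; estimates will be extremely noisy", stacklevel=2)
    values = np.empty((n, v), dtype=np.int64)
    levels = np.empty(v, dtype=np.int64)
    categories: list[list[str]] = []
    for j, col in enumerate(df.columns):
        labels = sorted(set(df[col]))
        if len(labels) == 1:
            warnings.warn(f"variable {names[j]!r} is constant", stacklevel=2)
        lookup = {lab: k for k, lab in enumerate(labels)}
        values[:, j] = df[col].map(lookup).to_numpy()
        levels[j] = len(labels)
        categories.append(labels)
    return CategoricalDataset(values, names, levels, categories)


def save_table(data: CategoricalDataset, path, delimiter: str = "\t") -> None:
    data.to_frame().to_csv(path, sep=delimiter, index=False)


def count_joint(data: CategoricalDataset, variables) -> ContingencyTable:
    """Joint counts over an ordered subset of variable indices.

    The empty subset yields a single empty-state count of N.
    """
    variables = tuple(int(v) for v in variables)
    if len(set(variables)) != len(variables):
        raise ValueError("variable indices must be distinct")
    for v in variables:
        if not 0 <= v < data.n_variables:
            raise IndexError(f"variable index {v} out of range")
    if not variables:
        return ContingencyTable((), {(): data.n_samples}, data.n_samples)
    sub = data.values[:, list(variables)]
    states, counts = np.unique(sub, axis=0, return_counts=True)
    table = {tuple(int(c) for c in row): int(n) for row, n in zip(states, counts)}
    return ContingencyTable(variables, table, data.n_samples)


def joint_count_vector(data: CategoricalDataset, variables) -> np.ndarray:
    """Dense nonzero count vector over joint states (fast path for entropies)."""
    codes, n_states = data.joint_codes(variables)
    counts = np.bincount(codes, minlength=min(n_states, codes.max() + 1 if codes.size else 1))
    return counts[counts > 0]
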