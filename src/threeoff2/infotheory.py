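"""Plug-in entropy, (conditional) mutual information and 3-point information.

Everything is estimated with the maximum-likelihood (plug-in) estimator on
observed joint counts, in nats.  The 3-point information

    I(x;y;z|{u}) = I(x;y|{u}) - I(x;y|z,{u})

is symmetric under permutations of x, y, z and may take either sign: negative
values favour a collider (v-structure) on the triple, positive values favour
the Markov-equivalent chain/fork alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import CategoricalDataset, ContingencyTable

__all__ = [
    "InformationValue",
    "entropy",
    "entropy_of",
    "conditional_mutual_information",
    "mutual_information",
    "three_point_information",
    "decompose",
]

#: tolerance below which small negative CMI from floating-point cancellation is clamped
NEG_TOL = 1e-12


@dataclass(frozen=True)
class InformationValue:
    value: float
    n_effective: int

    def __float__(self) -> float:
        return self.value


def _entropy_from_counts(counts: np.ndarray, total: int) -> float:
    # H = ln(total) - (1/total) * sum n ln n ; zero cells contribute 0
    counts = counts[counts > 0]
    if total <= 0:
        raise ValueError("entropy of an empty table is undefined")
    return float(np.log(total) - np.dot(counts, np.log(counts)) / total)


def entropy(table: ContingencyTable) -> InformationValue:
    """Plug-in entropy H = -sum (n_s/N) ln(n_s/N) of a contingency table, in nats."""
    if table.total < 1 or not table.counts:
        raise ValueError("entropy of an empty table is undefined")
    return InformationValue(_entropy_from_counts(table.count_vector(), table.total), table.total)


def entropy_of(data: CategoricalDataset, variables) -> float:
    """Joint plug-in entropy of a variable subset (fast path)."""
    codes, _ = data.joint_codes(variables)
    counts = np.bincount(codes)
    return _entropy_from_counts(counts, data.n_samples)


def _check_disjoint(*groups):
    seen = set()
    for g in groups:
        for v in g:
            if v in seen:
                raise ValueError("variable indices overlap")
            seen.add(v)


def conditional_mutual_information(
    data: CategoricalDataset, x: int, y: int, cond=()
) -> InformationValue:
    """I(x;y|{u}) = H(x,{u}) + H(y,{u}) - H(x,y,{u}) - H({u}), clamped at 0.

    With an empty conditioning set this reduces to the mutual information
    I(x;y) = H(x) + H(y) - H(x,y).  Tiny negative values arising from
    floating-point cancellation are clamped to zero.
    """
    cond = list(cond)
    _check_disjoint([x], [y], cond)
    h_xu = entropy_of(data, [x] + cond)
    h_yu = entropy_of(data, [y] + cond)
    h_xyu = entropy_of(data, [x, y] + cond)
    h_u = entropy_of(data, cond) if cond else 0.0
    value = h_xu + h_yu - h_xyu - h_u
    if value < 0:
        if value < -1e-9:
            raise AssertionError(f"CMI estimate {value} is negative beyond tolerance")
        value = 0.0
    return InformationValue(value, data.n_samples)


def mutual_information(data: CategoricalDataset, x: int, y: int) -> InformationValue:
    return conditional_mutual_information(data, x, y, ())


def three_point_information(
    data: CategoricalDataset, x: int, y: int, z: int, cond=()
) -> InformationValue:
    """I(x;y;z|{u}) = I(x;y|{u}) - I(x;y|z,{u}); sign-informative, xyz-symmetric."""
    cond = list(cond)
    _check_disjoint([x], [y], [z], cond)
    i_xy_u = conditional_mutual_information(data, x, y, cond)
    i_xy_zu = conditional_mutual_information(data, x, y, [z] + cond)
    return InformationValue(i_xy_u.value - i_xy_zu.value, data.n_samples)


def decompose(data: CategoricalDataset, x: int, y: int, contributors=()) -> list[float]:
    """Chain decomposition of I(x;y) over an ordered contributor list.

    Returns ``[I(x;y;u1), I(x;y;u2|u1), ..., I(x;y;un|{u}_{n-1}), I(x;y|{u}_n)]``
    whose terms telescope to I(x;y) exactly.  The final residual term depends
    only on the contributor *set*, not on its order.
    """
    contributors = list(contributors)
    _check_disjoint([x], [y], contributors)
    terms: list[float] = []
    cond: list[int] = []
    for u in contributors:
        terms.append(three_point_information(data, x, y, u, cond).value)
        cond.append(u)
    terms.append(conditional_mutual_information(data, x, y, cond).value)
    return terms
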