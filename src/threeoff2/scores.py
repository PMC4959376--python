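"""Shifted information, v/non-v structure probabilities and the edge rank.

The finite-size decision rules replace raw information by complexity-shifted
equivalents,

    I'(x;y|{u})   = I(x;y|{u})   - k_{x;y|{u}}/N
    I'(x;y;z|{u}) = I(x;y;z|{u}) + k_{x;y;z|{u}}/N

so that I'(x;y|{u}) < 0 signals a structural independency and
I'(x;y;z|{u}) < 0 signals that a v-structure on the triple is more likely
than the Markov-equivalent non-v alternatives.  Probabilities are logistic
functions of N times these quantities, always evaluated in the log domain.

``rank_mode`` selects which information terms feed the probabilities:
``"shifted"`` (recommended with the NML score) or ``"raw"`` (recommended with
MDL on finite data, where the shifted terms over-penalize many-level
variables).  ``"auto"`` resolves per score kind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .complexity import pair_complexity, three_point_complexity
from .dataset import CategoricalDataset
from .infotheory import conditional_mutual_information, three_point_information

__all__ = [
    "TripleScore",
    "resolve_rank_mode",
    "shifted_information",
    "prob_non_v",
    "prob_base",
    "contribution_score",
    "best_contributor",
]


def resolve_rank_mode(rank_mode: str, score_kind: str) -> str:
    if rank_mode == "auto":
        return "shifted" if score_kind == "nml" else "raw"
    if rank_mode not in ("shifted", "raw"):
        raise ValueError(f"unknown rank mode {rank_mode!r}")
    return rank_mode


@dataclass(frozen=True)
class TripleScore:
    x: int
    y: int
    z: int
    cond: tuple[int, ...]
    I2: float
    I2_shifted: float
    I3: float
    I3_shifted: float
    p_nv: float
    p_base: float
    s_lb: float


def shifted_information(
    data: CategoricalDataset, x: int, y: int, z=None, u=(), score_kind: str = "nml"
) -> tuple[float, float | None]:
    """(I'(x;y|{u}), I'(x;y;z|{u})); the 3-point term is None when z is None."""
    u = list(u)
    n = data.n_samples
    i2 = conditional_mutual_information(data, x, y, u).value
    k2 = pair_complexity(data, x, y, u, score_kind).value
    i2s = i2 - k2 / n
    if z is None:
        return i2s, None
    i3 = three_point_information(data, x, y, z, u).value
    k3 = three_point_complexity(data, x, y, z, u, score_kind).value
    return i2s, i3 + k3 / n


def _info2(data, x, y, u, score_kind, rank_mode) -> float:
    i2 = conditional_mutual_information(data, x, y, u).value
    if rank_mode == "raw":
        return i2
    return i2 - pair_complexity(data, x, y, u, score_kind).value / data.n_samples


def _info3(data, x, y, z, u, score_kind, rank_mode) -> float:
    i3 = three_point_information(data, x, y, z, u).value
    if rank_mode == "raw":
        return i3
    return i3 + three_point_complexity(data, x, y, z, u, score_kind).value / data.n_samples


def prob_non_v(
    data: CategoricalDataset,
    x: int,
    y: int,
    z: int,
    u=(),
    score_kind: str = "nml",
    rank_mode: str = "shifted",
) -> float:
    """P_nv = 1 / (1 + exp(-N I'(x;y;z|{u}))): probability the triple is a
    generalized non-v-structure; > 1/2 iff the (mode-selected) 3-point term is > 0."""
    rank_mode = resolve_rank_mode(rank_mode, score_kind)
    i3 = _info3(data, x, y, z, list(u), score_kind, rank_mode)
    return float(expit(data.n_samples * i3))


def prob_base(
    data: CategoricalDataset,
    x: int,
    y: int,
    z: int,
    u=(),
    score_kind: str = "nml",
    rank_mode: str = "shifted",
) -> float:
    """Probability that xy (rather than xz or yz) is the base of the triple.

    Softmax of -N I'(s;t|{u}) over the three pairs: the least-correlated pair,
    conditioned on {u}, is the most likely base (consistent with the Data
    Processing Inequality for non-v-structures).
    """
    rank_mode = resolve_rank_mode(rank_mode, score_kind)
    u = list(u)
    n = data.n_samples
    w = -n * np.array(
        [
            _info2(data, x, y, u, score_kind, rank_mode),
            _info2(data, x, z, u, score_kind, rank_mode),
            _info2(data, y, z, u, score_kind, rank_mode),
        ]
    )
    w -= w.max()
    e = np.exp(w)
    return float(e[0] / e.sum())


def contribution_score(
    data: CategoricalDataset,
    x: int,
    y: int,
    z: int,
    u=(),
    score_kind: str = "nml",
    rank_mode: str = "shifted",
) -> TripleScore:
    """Lower-bound score S_lb(z;xy|{u}) = min(P_nv, P_b) and the full triple record."""
    rank_mode = resolve_rank_mode(rank_mode, score_kind)
    u = list(u)
    n = data.n_samples
    i2 = conditional_mutual_information(data, x, y, u).value
    k2 = pair_complexity(data, x, y, u, score_kind).value
    i3 = three_point_information(data, x, y, z, u).value
    k3 = three_point_complexity(data, x, y, z, u, score_kind).value
    p_nv = prob_non_v(data, x, y, z, u, score_kind, rank_mode)
    p_b = prob_base(data, x, y, z, u, score_kind, rank_mode)
    return TripleScore(
        x=x,
        y=y,
        z=z,
        cond=tuple(u),
        I2=i2,
        I2_shifted=i2 - k2 / n,
        I3=i3,
        I3_shifted=i3 + k3 / n,
        p_nv=p_nv,
        p_base=p_b,
        s_lb=min(p_nv, p_b),
    )


def best_contributor(
    data: CategoricalDataset,
    x: int,
    y: int,
    u=(),
    candidates=(),
    score_kind: str = "nml",
    rank_mode: str = "shifted",
):
    """argmax_z S_lb(z;xy|{u}) over eligible candidates, and the rank value.

    A candidate is eligible only when its (mode-selected) 3-point contribution
    is strictly positive — negative contributions signal v-structures, not
    indirect paths.  Ties are broken by lexicographic variable name; returns
    (None, 0.0) when nothing is eligible.
    """
    rank_mode = resolve_rank_mode(rank_mode, score_kind)
    u = list(u)
    best: tuple[str, int] | None = None
    best_rank = 0.0
    for z in candidates:
        if z in u or z in (x, y):
            continue
        i3 = _info3(data, x, y, z, u, score_kind, rank_mode)
        if i3 <= 0:
            continue
        s = contribution_score(data, x, y, z, u, score_kind, rank_mode).s_lb
        name = data.variable_names[z]
        if best is None or s > best_rank or (s == best_rank and name < best[0]):
            best = (name, z)
            best_rank = s
    if best is None:
        return None, 0.0
    return best[1], best_rank
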