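"""Skeleton reconstruction by iterative take-off of 3-point information.

Starting from the complete undirected graph, the scheme repeatedly picks the
edge xy with the highest rank R(xy;z|{u}) — the most confident indirect
contribution of some node z to the pairwise dependence of x and y — moves
that z into the pair's conditioning set, and re-evaluates the shifted
conditional 2-point information I'(x;y|{u}).  An edge is deleted as soon as a
structural independency is found, I'(x;y|{u}) < 0, and the accumulated
contributors become the pair's separation set.  No adjustable significance
level is involved: 1/N and the complexity terms set the scale.

Candidate contributors for an edge xy are the current neighbors of x or y in
the shrinking graph, which keeps the search polynomial on sparse graphs.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from .dataset import CategoricalDataset
from .graphs import MixedGraph
from .infotheory import conditional_mutual_information, three_point_information
from .complexity import pair_complexity
from .scores import best_contributor, resolve_rank_mode

__all__ = ["EdgeState", "SkeletonResult", "reconstruct_skeleton"]


@dataclass
class EdgeState:
    """Mutable per-edge bookkeeping during the take-off iteration."""

    x: int
    y: int
    cond_set: list[int] = field(default_factory=list)
    I2: float = 0.0
    I2_shifted: float = 0.0
    best_z: int | None = None
    rank: float = 0.0
    status: str = "active"  # active | removed | settled
    takeoffs: list[float] = field(default_factory=list)  # raw I3 terms removed so far
    version: int = 0


@dataclass
class SkeletonResult:
    graph: MixedGraph
    sepsets: dict  # frozenset({name_a, name_b}) -> tuple of separator names (in order found)
    edge_states: dict  # (i, j) index pair -> EdgeState
    trace: list  # ordered (event, edge, detail) log


def _shifted_i2(data, x, y, cond, score_kind):
    i2 = conditional_mutual_information(data, x, y, cond).value
    k2 = pair_complexity(data, x, y, cond, score_kind).value
    return i2, i2 - k2 / data.n_samples


def reconstruct_skeleton(
    data: CategoricalDataset,
    score_kind: str = "nml",
    rank_mode: str = "auto",
    max_cond_size: int | None = None,
) -> SkeletonResult:
    """Step 1 of the reconstruction: undirected skeleton plus separation sets.

    ``score_kind`` selects the complexity term ('nml' or 'mdl'); ``rank_mode``
    selects shifted or raw information in the edge ranks (auto: shifted with
    NML, raw with MDL).  The independence test that actually deletes an edge
    is the shifted criterion I'(x;y|{u}) < 0 in either mode.
    ``max_cond_size`` caps the conditioning-set size (None = unbounded).
    """
    if data.n_samples < 2 or data.n_variables < 2:
        raise ValueError("need at least 2 samples and 2 variables")
    rank_mode = resolve_rank_mode(rank_mode, score_kind)
    names = data.variable_names
    order = sorted(range(data.n_variables), key=lambda i: names[i])

    graph = MixedGraph(names)
    sepsets: dict = {}
    states: dict[tuple[int, int], EdgeState] = {}
    trace: list = []

    def pair_key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if names[i] < names[j] else (j, i)

    # -- initialization: prune marginally independent pairs -----------------
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            i, j = order[a], order[b]
            st = EdgeState(x=i, y=j)
            states[(i, j)] = st
            if data.levels[i] < 2 or data.levels[j] < 2:
                # a constant variable carries no information; trivially separated
                st.status = "removed"
                sepsets[frozenset((names[i], names[j]))] = ()
                trace.append(("init_remove", (names[i], names[j]), "constant variable"))
                continue
            st.I2, st.I2_shifted = _shifted_i2(data, i, j, [], score_kind)
            if st.I2_shifted < 0:
                st.status = "removed"
                sepsets[frozenset((names[i], names[j]))] = ()
                trace.append(("init_remove", (names[i], names[j]), st.I2_shifted))
            else:
                graph.add_edge(names[i], names[j])

    def candidates_for(st: EdgeState) -> list[int]:
        nx_, ny_ = names[st.x], names[st.y]
        cand_names = (graph.neighbors(nx_) | graph.neighbors(ny_)) - {nx_, ny_}
        cand = [data.index_of(c) for c in sorted(cand_names)]
        return [c for c in cand if c not in st.cond_set]

    heap: list = []  # (-rank, name_x, name_y, name_z, version, key)

    def push_fresh(st: EdgeState, key) -> None:
        """Recompute the best contributor; queue the edge or settle it."""
        if max_cond_size is not None and len(st.cond_set) >= max_cond_size:
            st.best_z, st.rank, st.status = None, 0.0, "settled"
            return
        z, rank = best_contributor(
            data, st.x, st.y, st.cond_set, candidates_for(st), score_kind, rank_mode
        )
        if z is None:
            st.best_z, st.rank, st.status = None, 0.0, "settled"
            return
        st.best_z, st.rank, st.status = z, rank, "active"
        st.version += 1
        heapq.heappush(
            heap, (-rank, names[st.x], names[st.y], names[z], st.version, key)
        )

    for key, st in states.items():
        if st.status != "removed":
            push_fresh(st, key)

    # -- main loop: take off the top-ranked contribution --------------------
    while heap:
        neg_rank, _, _, z_name, version, key = heapq.heappop(heap)
        st = states[key]
        if st.status == "removed":
            continue
        if version != st.version or st.best_z is None or names[st.best_z] != z_name:
            if st.status == "active":
                push_fresh(st, key)  # stale entry: re-rank against current graph
            continue

        z = st.best_z
        st.cond_set.append(z)
        st.takeoffs.append(three_point_information(data, st.x, st.y, z, st.cond_set[:-1]).value)
        st.I2, st.I2_shifted = _shifted_i2(data, st.x, st.y, st.cond_set, score_kind)
        trace.append(("takeoff", (names[st.x], names[st.y]), (z_name, -neg_rank, st.I2_shifted)))

        if st.I2_shifted < 0:
            st.status = "removed"
            graph.remove_edge(names[st.x], names[st.y])
            sepsets[frozenset((names[st.x], names[st.y]))] = tuple(
                names[u] for u in st.cond_set
            )
            trace.append(("remove", (names[st.x], names[st.y]), tuple(st.cond_set)))
            # candidate sets only change for edges incident to the removed
            # edge's endpoints: invalidate their queued ranks (lazy
            # revalidation on pop)
            for other_key, other in states.items():
                if other.status != "active" or other_key == key:
                    continue
                if {st.x, st.y} & {other.x, other.y}:
                    other.version += 1
        else:
            push_fresh(st, key)

    return SkeletonResult(graph=graph, sepsets=sepsets, edge_states=states, trace=trace)
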