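"""Edge orientation by ranked likelihood of v-structures and propagations.

Unshielded triples x-z-y (x, y non-adjacent) are scored once by the shifted
conditional 3-point information I'(x;y;z|{u}), conditioning on the pair's
separation set with z excluded.  Sweeping the triples in decreasing |I'|:

* I' < 0 orients a v-structure x->z<-y (rule R0), unless either arrowhead
  contradicts an existing orientation, in which case the less likely
  v-structure is skipped entirely;
* I' > 0 licenses propagation (rule R1): with one link already directed into
  z and the other undirected, the undirected link is directed away from z
  (a second head at z would create an unsanctioned v-structure).

Sweeps repeat until a full pass changes nothing.  Rules R2/R3 are deliberately
not applied — they enforce acyclicity rather than a likelihood preference —
so the output PDAG may contain directed cycles.  An arrowhead, once placed,
is never reversed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .dataset import CategoricalDataset
from .complexity import three_point_complexity
from .graphs import MixedGraph
from .infotheory import three_point_information
from .skeleton import SkeletonResult

__all__ = ["OrientedTriple", "unshielded_triples", "orient"]


@dataclass
class OrientedTriple:
    x: str
    z: str
    y: str
    cond: tuple[str, ...]
    I3_shifted: float
    verdict: str = "unused"  # unused | v_structure | non_v | skipped_conflict


def unshielded_triples(graph: MixedGraph) -> list[tuple[str, str, str]]:
    """All triples x-z-y with x,y non-adjacent, canonical (x < y), each once."""
    out = []
    for z in sorted(graph.nodes):
        for x, y in combinations(sorted(graph.neighbors(z)), 2):
            if not graph.has_edge(x, y):
                out.append((x, z, y))
    return out


def score_triples(
    skel: SkeletonResult, data: CategoricalDataset, score_kind: str = "nml"
) -> list[OrientedTriple]:
    """Score every unshielded triple by shifted 3-point information."""
    n = data.n_samples
    triples = []
    for x, z, y in unshielded_triples(skel.graph):
        sep = skel.sepsets.get(frozenset((x, y)), ())
        cond_names = tuple(u for u in sep if u != z)
        cond = [data.index_of(u) for u in cond_names]
        ix, iy, iz = data.index_of(x), data.index_of(y), data.index_of(z)
        i3 = three_point_information(data, ix, iy, iz, cond).value
        k3 = three_point_complexity(data, ix, iy, iz, cond, score_kind).value
        triples.append(OrientedTriple(x, z, y, cond_names, i3 + k3 / n))
    return triples


def _can_head(graph: MixedGraph, tail: str, head: str) -> bool:
    """True if placing tail->head does not contradict an existing orientation."""
    return not graph.is_directed_edge(head, tail)


def orient(
    skel: SkeletonResult,
    data: CategoricalDataset,
    score_kind: str = "nml",
    rank_mode: str = "auto",
) -> MixedGraph:
    """Step 2 of the reconstruction: partially direct the skeleton.

    Returns a PDAG; edges not reached by R0/R1 stay undirected.  ``rank_mode``
    is accepted for interface symmetry with the skeleton step; the triple
    scores here always use the shifted 3-point information, whose sign is the
    likelihood-ratio test for v-structure vs non-v-structure.
    """
    graph = skel.graph.copy()
    triples = score_triples(skel, data, score_kind)
    # decreasing |I'|, deterministic tie-break on names
    triples.sort(key=lambda t: (-abs(t.I3_shifted), t.z, t.x, t.y))

    changed = True
    while changed:
        changed = False
        for t in triples:
            if t.verdict != "unused" or t.I3_shifted == 0.0:
                continue
            if t.I3_shifted < 0:
                # R0: v-structure x -> z <- y
                if _can_head(graph, t.x, t.z) and _can_head(graph, t.y, t.z):
                    placed = False
                    if not graph.is_directed_edge(t.x, t.z):
                        graph.orient(t.x, t.z)
                        placed = True
                    if not graph.is_directed_edge(t.y, t.z):
                        graph.orient(t.y, t.z)
                        placed = True
                    t.verdict = "v_structure"
                    changed = changed or placed
                else:
                    t.verdict = "skipped_conflict"
            else:
                # R1 on a non-v triple: one head into z, other link undirected
                for a, b in ((t.x, t.y), (t.y, t.x)):
                    if graph.is_directed_edge(a, t.z) and graph.is_undirected_edge(t.z, b):
                        graph.orient(t.z, b)
                        t.verdict = "non_v"
                        changed = True
                        break
                else:
                    # both links already head into z: the licensed propagation
                    # would contradict an existing orientation — skip for good
                    if graph.is_directed_edge(t.x, t.z) and graph.is_directed_edge(t.y, t.z):
                        t.verdict = "skipped_conflict"
    return graph
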