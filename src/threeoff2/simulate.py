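"""Synthetic data: discrete Bayesian networks, ancestral sampling, fixtures.

A :class:`BayesNet` is a DAG over named nodes with per-node level counts and
conditional probability tables (CPTs).  Forward (ancestral) sampling in
topological order produces :class:`~threeoff2.dataset.CategoricalDataset`
objects, so every stage of the reconstruction is testable without external
downloads.

Named fixtures cover the canonical three- and four-node structures (chain,
fork, collider with and without a child) with hand-set CPTs chosen for strong
dependence, plus an 8-node "mini-benchmark" (average degree 2.5, maximum
in-degree 2) whose reference CPDAG follows from the DAG.  Collider CPTs are
deliberately asymmetric so each parent also leaves a marginal footprint on
the child — a perfectly symmetric XOR gate would erase all pairwise signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .dataset import CategoricalDataset
from .graphs import MixedGraph

__all__ = ["BayesNet", "sample", "random_dag", "fixtures", "load_network", "save_network"]


@dataclass(frozen=True)
class BayesNet:
    """DAG + levels + CPTs.

    ``cpts[node]`` has shape (q, r): one row per joint parent state (mixed-radix
    index over ``parents[node]`` in listed order, first parent varying slowest),
    each row a distribution over the node's r levels.
    """

    nodes: tuple[str, ...]
    parents: dict  # node -> tuple of parent names
    levels: dict  # node -> int
    cpts: dict  # node -> np.ndarray (q, r)

    def __post_init__(self):
        for node in self.nodes:
            r = self.levels[node]
            q = int(np.prod([self.levels[p] for p in self.parents[node]])) if self.parents[node] else 1
            cpt = np.asarray(self.cpts[node], dtype=float)
            if cpt.shape != (q, r):
                raise ValueError(f"CPT for {node} must have shape ({q}, {r}), got {cpt.shape}")
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows for {node} must sum to 1")
            if np.any(cpt < 0):
                raise ValueError(f"CPT for {node} has negative entries")
        if self.topological_order() is None:
            raise ValueError("parent structure is cyclic")

    def topological_order(self):
        indeg = {n: len(self.parents[n]) for n in self.nodes}
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for n in self.nodes:
            for p in self.parents[n]:
                children[p].append(n)
        ready = sorted(n for n, d in indeg.items() if d == 0)
        order = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
            ready.sort()
        return order if len(order) == len(self.nodes) else None

    def dag(self) -> MixedGraph:
        g = MixedGraph(self.nodes)
        for node in self.nodes:
            for p in self.parents[node]:
                g.add_edge(p, node, directed=True)
        return g


def sample(net: BayesNet, n: int, seed: int) -> CategoricalDataset:
    """Ancestral sampling: draw each node given its parents, in topological order."""
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    order = net.topological_order()
    cols = {}
    for node in order:
        pars = net.parents[node]
        cpt = np.asarray(net.cpts[node], dtype=float)
        if pars:
            dims = tuple(net.levels[p] for p in pars)
            idx = np.ravel_multi_index(tuple(cols[p] for p in pars), dims)
        else:
            idx = np.zeros(n, dtype=np.int64)
        cum = np.cumsum(cpt, axis=1)
        u = rng.random(n)
        cols[node] = (u[:, None] > cum[idx]).sum(axis=1).astype(np.int64)
    names = list(net.nodes)
    values = np.column_stack([cols[name] for name in names])
    levels = np.array([net.levels[name] for name in names], dtype=np.int64)
    categories = [[str(k) for k in range(net.levels[name])] for name in names]
    return CategoricalDataset(values, names, levels, categories)


def random_dag(
    n_nodes: int,
    avg_degree: float = 2.5,
    max_in_degree: int = 2,
    levels_range: tuple[int, int] = (2, 2),
    dirichlet_alpha: float = 0.5,
    seed: int = 0,
    cpt_style: str = "dirichlet",
) -> BayesNet:
    """Random DAG with target average degree, bounded in-degree, random CPTs.

    Nodes get a uniform-random topological order; edges are drawn uniformly
    from the pairs consistent with that order until ``round(avg_degree *
    n_nodes / 2)`` edges are placed without exceeding ``max_in_degree``.

    ``cpt_style='dirichlet'`` draws each CPT row from a symmetric Dirichlet —
    faithful to typical benchmark tables but allowing near-degenerate rows
    and hence occasionally undetectable edges.  ``cpt_style='logistic'``
    builds rows from a multinomial-logistic model whose per-parent weights
    are bounded away from zero, guaranteeing every edge a strong signal.
    """
    rng = np.random.default_rng(seed)
    n_edges = int(round(avg_degree * n_nodes / 2.0))
    if max_in_degree * (n_nodes - 1) < n_edges or n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("infeasible degree constraints")
    names = [f"X{i:02d}" for i in range(n_nodes)]
    order = list(rng.permutation(n_nodes))
    pairs = [(order[i], order[j]) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    rng.shuffle(pairs)
    parents: dict[str, list[str]] = {name: [] for name in names}
    placed = 0
    for a, b in pairs:
        if placed == n_edges:
            break
        if len(parents[names[b]]) < max_in_degree:
            parents[names[b]].append(names[a])
            placed += 1
    if placed < n_edges:
        raise ValueError("could not place the requested number of edges")
    lo, hi = levels_range
    levels = {name: int(rng.integers(lo, hi + 1)) for name in names}
    cpts = {}
    for name in names:
        pars = parents[name]
        q = int(np.prod([levels[p] for p in pars])) if pars else 1
        r = levels[name]
        if cpt_style == "dirichlet":
            cpts[name] = rng.dirichlet([dirichlet_alpha] * r, size=q)
        elif cpt_style == "logistic":
            # score_k = w0_k + c_k * sum_i m_i * centered(parent_i), with level
            # scores c_k centered and |m_i| in [1, 2.5]: every parent shifts the
            # child's log-odds by at least 1 between adjacent levels
            w0 = rng.uniform(-0.5, 0.5, size=r)
            c = np.arange(r) - (r - 1) / 2.0
            m = rng.uniform(1.0, 2.5, size=len(pars)) * rng.choice(
                [-1.0, 1.0], size=len(pars)
            )
            rows = np.empty((q, r))
            dims = [levels[p] for p in pars]
            for j in range(q):
                state = np.unravel_index(j, dims) if pars else ()
                centered = [s - (d - 1) / 2.0 for s, d in zip(state, dims)]
                score = w0 + c * float(np.dot(m, centered)) if pars else w0
                e = np.exp(score - score.max())
                rows[j] = e / e.sum()
            cpts[name] = rows
        else:
            raise ValueError(f"unknown cpt_style {cpt_style!r}")
    return BayesNet(
        nodes=tuple(names),
        parents={k: tuple(v) for k, v in parents.items()},
        levels=levels,
        cpts=cpts,
    )


def _copy_cpt(p_same: float) -> np.ndarray:
    """Binary child copying a binary parent with fidelity p_same."""
    return np.array([[p_same, 1 - p_same], [1 - p_same, p_same]])


#: tilted near-XOR collider gate: P(child=1 | parents), parent states in order
#: (0,0), (0,1), (1,0), (1,1).  The tilt gives each parent a clear marginal
#: signature on the child while keeping the explaining-away signal strong.
_COLLIDER_P1 = np.array([0.05, 0.75, 0.85, 0.50])


def _collider_cpt() -> np.ndarray:
    p1 = _COLLIDER_P1
    return np.column_stack([1 - p1, p1])


def fixtures() -> dict[str, BayesNet]:
    """Named small networks with hand-set CPTs and known CPDAGs."""
    uniform = np.array([[0.5, 0.5]])
    nets = {}

    nets["chain"] = BayesNet(
        nodes=("x", "z", "y"),
        parents={"x": (), "z": ("x",), "y": ("z",)},
        levels={"x": 2, "z": 2, "y": 2},
        cpts={"x": uniform, "z": _copy_cpt(0.85), "y": _copy_cpt(0.85)},
    )
    nets["fork"] = BayesNet(
        nodes=("z", "x", "y"),
        parents={"z": (), "x": ("z",), "y": ("z",)},
        levels={"z": 2, "x": 2, "y": 2},
        cpts={"z": uniform, "x": _copy_cpt(0.85), "y": _copy_cpt(0.85)},
    )
    nets["v_structure"] = BayesNet(
        nodes=("x", "y", "z"),
        parents={"x": (), "y": (), "z": ("x", "y")},
        levels={"x": 2, "y": 2, "z": 2},
        cpts={"x": uniform, "y": uniform, "z": _collider_cpt()},
    )
    nets["collider_plus_child"] = BayesNet(
        nodes=("x", "y", "z", "w"),
        parents={"x": (), "y": (), "z": ("x", "y"), "w": ("z",)},
        levels={"x": 2, "y": 2, "z": 2, "w": 2},
        cpts={"x": uniform, "y": uniform, "z": _collider_cpt(), "w": _copy_cpt(0.85)},
    )

    # 8-node mini-benchmark: 10 edges, average degree 2.5, max in-degree 2,
    # mixing colliders (C, F, G, H) with chain segments.
    mb_parents = {
        "A": (),
        "B": (),
        "C": ("A", "B"),
        "D": ("C",),
        "E": ("C",),
        "F": ("D", "E"),
        "G": ("E", "A"),
        "H": ("G", "B"),
    }
    mb_cpts = {
        "A": uniform,
        "B": uniform,
        "C": _collider_cpt(),
        "D": _copy_cpt(0.85),
        "E": _copy_cpt(0.85),
        "F": _collider_cpt(),
        "G": _collider_cpt(),
        "H": _collider_cpt(),
    }
    nets["mini_benchmark"] = BayesNet(
        nodes=tuple(sorted(mb_parents)),
        parents=mb_parents,
        levels={n: 2 for n in mb_parents},
        cpts=mb_cpts,
    )
    return nets


def save_network(net: BayesNet, path) -> None:
    """Serialize a network to the package's JSON schema."""
    doc = {
        "nodes": list(net.nodes),
        "levels": {n: int(net.levels[n]) for n in net.nodes},
        "parents": {n: list(net.parents[n]) for n in net.nodes},
        "cpt": {n: np.asarray(net.cpts[n]).tolist() for n in net.nodes},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_network(path) -> BayesNet:
    with open(path) as fh:
        doc = json.load(fh)
    return BayesNet(
        nodes=tuple(doc["nodes"]),
        parents={n: tuple(ps) for n, ps in doc["parents"].items()},
        levels={n: int(r) for n, r in doc["levels"].items()},
        cpts={n: np.asarray(rows, dtype=float) for n, rows in doc["cpt"].items()},
    )
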