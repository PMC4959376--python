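"""End-to-end reconstruction: skeleton + orientation in one call."""

from __future__ import annotations

from dataclasses import dataclass

from .dataset import CategoricalDataset
from .graphs import MixedGraph
from .orientation import orient
from .skeleton import SkeletonResult, reconstruct_skeleton

__all__ = ["ReconstructionResult", "reconstruct"]


@dataclass
class ReconstructionResult:
    pdag: MixedGraph
    skeleton: SkeletonResult


def reconstruct(
    data: CategoricalDataset,
    score_kind: str = "nml",
    rank_mode: str = "auto",
    max_cond_size: int | None = None,
    skeleton_only: bool = False,
) -> ReconstructionResult:
    """Reconstruct a partially directed graph from categorical observations.

    Runs the take-off skeleton search, then (unless ``skeleton_only``) the
    likelihood-ranked orientation/propagation sweep.
    """
    skel = reconstruct_skeleton(data, score_kind, rank_mode, max_cond_size)
    if skeleton_only:
        return ReconstructionResult(pdag=skel.graph.copy(), skeleton=skel)
    pdag = orient(skel, data, score_kind, rank_mode)
    return ReconstructionResult(pdag=pdag, skeleton=skel)
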