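"""Skeleton and orientation-aware precision / recall / F-score.

Skeleton metrics compare unordered adjacencies.  CPDAG metrics additionally
reclassify every skeleton-true edge whose orientation status disagrees with
the reference CPDAG (directed vs undirected, or oppositely directed) as a
false positive:

    TP' = TP - TP_misorient,    FP' = FP + TP_misorient

with Prec' = TP'/(TP'+FP'), Rec' = TP'/(TP+FN) and the usual harmonic F.
Empty-prediction conventions: 0/0 ratios are reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graphs import MixedGraph

__all__ = ["EvaluationReport", "skeleton_scores", "cpdag_scores"]


@dataclass(frozen=True)
class EvaluationReport:
    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    fscore: float
    TP_misorient: int | None = None
    precision_cpdag: float | None = None
    recall_cpdag: float | None = None
    fscore_cpdag: float | None = None
    undefined_precision: bool = False

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def _fscore(prec: float, rec: float) -> float:
    return _ratio(2.0 * prec * rec, prec + rec)


def _check_nodes(predicted: MixedGraph, reference: MixedGraph) -> None:
    if set(predicted.nodes) != set(reference.nodes):
        raise ValueError("predicted and reference graphs must share the same node set")


def skeleton_scores(predicted: MixedGraph, reference: MixedGraph) -> EvaluationReport:
    """Precision/recall/F of predicted adjacencies against the reference skeleton."""
    _check_nodes(predicted, reference)
    pred = predicted.skeleton_pairs()
    ref = reference.skeleton_pairs()
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    prec = _ratio(tp, tp + fp)
    rec = _ratio(tp, tp + fn)
    return EvaluationReport(
        TP=tp,
        FP=fp,
        FN=fn,
        precision=prec,
        recall=rec,
        fscore=_fscore(prec, rec),
        undefined_precision=(tp + fp == 0),
    )


def _orientation_status(g: MixedGraph, a: str, b: str):
    """None (undirected) or the (tail, head) direction of an existing edge."""
    if g.is_undirected_edge(a, b):
        return None
    return (a, b) if g.is_directed_edge(a, b) else (b, a)


def cpdag_scores(predicted: MixedGraph, reference_cpdag: MixedGraph) -> EvaluationReport:
    """Orientation-aware metrics against a reference CPDAG."""
    base = skeleton_scores(predicted, reference_cpdag)
    common = predicted.skeleton_pairs() & reference_cpdag.skeleton_pairs()
    tp_mis = sum(
        1
        for a, b in common
        if _orientation_status(predicted, a, b) != _orientation_status(reference_cpdag, a, b)
    )
    tp_p = base.TP - tp_mis
    fp_p = base.FP + tp_mis
    prec = _ratio(tp_p, tp_p + fp_p)
    rec = _ratio(tp_p, base.TP + base.FN)
    return EvaluationReport(
        TP=base.TP,
        FP=base.FP,
        FN=base.FN,
        precision=base.precision,
        recall=base.recall,
        fscore=base.fscore,
        TP_misorient=tp_mis,
        precision_cpdag=prec,
        recall_cpdag=rec,
        fscore_cpdag=_fscore(prec, rec),
        undefined_precision=base.undefined_precision,
    )
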