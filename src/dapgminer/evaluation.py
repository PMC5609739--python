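"""Benchmark metrics for predicted complexes against a gold standard.

Implements the standard clustering-comparison battery: overlap score,
FMeasure (precision/recall over OS-matched complexes), the Brohée-van
Helden sensitivity / positive predictive value / accuracy triple computed
from the reference x prediction overlap matrix, and the Maximum Matching
Ratio (MMR) of Nepusz et al., based on an exact maximum-weight one-to-one
matching between reference and predicted complexes.  Also provides the
ClusterONE-style reference filtering for proteins absent from the network,
perfect-match counting, and cumulative overlap histograms.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import linear_sum_assignment

from .network import ComplexSet, PPINetwork

__all__ = [
    "EvalConfig",
    "EvalReport",
    "overlap_score",
    "fmeasure_stats",
    "accuracy_stats",
    "mmr",
    "mmr_matching",
    "filter_reference",
    "perfect_match_count",
    "overlap_histogram",
    "evaluate",
]


@dataclass(frozen=True)
class EvalConfig:
    """Thresholds for the evaluation battery.

    match_threshold: minimum OS to call a predicted/reference pair a match
    (0.25 by convention; 0.2 is the other common choice).
    mmr_min_os: OS floor for edges of the MMR bipartite graph.
    """

    match_threshold: float = 0.25
    mmr_min_os: float = 0.2

    def __post_init__(self) -> None:
        for v in (self.match_threshold, self.mmr_min_os):
            if not 0.0 < v <= 1.0:
                raise ValueError("thresholds must be in (0, 1]")


@dataclass(frozen=True)
class EvalReport:
    """Bundle of all clustering metrics for one prediction run."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    fmeasure: float
    sn: float
    ppv: float
    acc: float
    mmr: float
    perfect_matches: int
    n_predicted: int
    n_reference: int

    def as_dict(self) -> dict[str, float | int]:
        return dict(self.__dict__)


def overlap_score(pc: frozenset[str], rc: frozenset[str]) -> float:
    """OS(pc, rc) = |pc n rc|^2 / (|pc| * |rc|); 1 iff the sets are equal."""
    if not pc or not rc:
        raise ValueError("overlap_score is undefined for empty sets")
    inter = len(pc & rc)
    return inter * inter / (len(pc) * len(rc))


def fmeasure_stats(
    pred: ComplexSet, ref: ComplexSet, w: float = 0.25
) -> tuple[float, float, float, int, int, int]:
    """Precision, recall and FMeasure at match threshold *w*.

    TP counts predicted complexes matching (OS >= w) some reference complex;
    FP the remaining predictions; FN the reference complexes matched by no
    prediction.  Returns (precision, recall, fmeasure, tp, fp, fn).
    """
    if len(pred) == 0 or len(ref) == 0:
        raise ValueError("fmeasure_stats requires nonempty prediction and reference")
    matched_ref = [False] * len(ref)
    tp = 0
    for pc in pred:
        hit = False
        for i, rc in enumerate(ref):
            if overlap_score(pc, rc) >= w:
                hit = True
                matched_ref[i] = True
        if hit:
            tp += 1
    fp = len(pred) - tp
    fn = matched_ref.count(False)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * recall * precision / (recall + precision) if precision + recall else 0.0
    return precision, recall, f, tp, fp, fn


def accuracy_stats(
    pred: ComplexSet,
    ref: ComplexSet,
    ppv_denominator: Literal["overlap", "size"] = "overlap",
) -> tuple[float, float, float]:
    """Sensitivity, PPV and their geometric mean (Acc).

    T_ij = |ref_i n pred_j|.  Sn = sum_i max_j T_ij / sum_i |ref_i|.
    PPV = sum_j max_i T_ij / D with D = sum_j sum_i T_ij (the
    Brohée-van Helden convention, default) or D = sum_j |pred_j| when
    ``ppv_denominator="size"``.  Predictions overlapping no reference
    contribute nothing to either PPV sum under the default.
    """
    if len(pred) == 0 or len(ref) == 0:
        raise ValueError("accuracy_stats requires nonempty prediction and reference")
    T = np.array([[len(rc & pc) for pc in pred] for rc in ref], dtype=float)
    n_i = np.array([len(rc) for rc in ref], dtype=float)
    sn = T.max(axis=1).sum() / n_i.sum()
    col_max = T.max(axis=0)
    if ppv_denominator == "overlap":
        denom = T.sum()
    elif ppv_denominator == "size":
        denom = float(sum(len(pc) for pc in pred))
    else:
        raise ValueError(f"unknown ppv_denominator: {ppv_denominator!r}")
    ppv = col_max.sum() / denom if denom else 0.0
    return float(sn), float(ppv), float(np.sqrt(sn * ppv))


def _os_matrix(ref: ComplexSet, pred: ComplexSet, min_os: float) -> np.ndarray:
    W = np.zeros((len(ref), len(pred)))
    for i, rc in enumerate(ref):
        for j, pc in enumerate(pred):
            os_ = overlap_score(pc, rc)
            if os_ >= min_os:
                W[i, j] = os_
    return W


def mmr_matching(
    pred: ComplexSet, ref: ComplexSet, min_os: float = 0.2
) -> list[tuple[int, int, float]]:
    """Optimal one-to-one (ref_i, pred_j, OS) pairs of the MMR matching.

    Edges exist only for pairs with OS >= min_os; the matching maximizes
    total OS (exact assignment, not a greedy per-reference argmax).
    """
    if len(ref) == 0:
        raise ValueError("reference set is empty")
    if len(pred) == 0:
        return []
    W = _os_matrix(ref, pred, min_os)
    rows, cols = linear_sum_assignment(W, maximize=True)
    return [(int(i), int(j), float(W[i, j])) for i, j in zip(rows, cols) if W[i, j] > 0]


def mmr(pred: ComplexSet, ref: ComplexSet, min_os: float = 0.2) -> float:
    """Maximum Matching Ratio: matched OS total / number of reference complexes."""
    pairs = mmr_matching(pred, ref, min_os)
    return sum(os_ for _, _, os_ in pairs) / len(ref)


def filter_reference(ref: ComplexSet, net: PPINetwork) -> ComplexSet:
    """Restrict a gold standard to the proteins present in the network.

    A reference complex with fewer than half of its members in the network
    is dropped (its prediction could never be attributed to the method);
    otherwise it is truncated to the members present.  Complexes reduced
    below two members are dropped as degenerate.
    """
    known = net.protein_set()
    out: list[frozenset[str]] = []
    labels: list[str] | None = [] if ref.labels is not None else None
    for i, rc in enumerate(ref):
        present = rc & known
        if len(present) < len(rc) / 2 or len(present) < 2:
            continue
        out.append(present)
        if labels is not None:
            labels.append(ref.labels[i])  # type: ignore[index]
    return ComplexSet(out, labels).deduplicated()


def perfect_match_count(pred: ComplexSet, ref: ComplexSet) -> int:
    """Number of predictions identical (OS = 1) to some reference complex."""
    ref_sets = ref.member_sets()
    return sum(1 for pc in pred if pc in ref_sets)


def overlap_histogram(
    pred: ComplexSet,
    ref: ComplexSet,
    min_os: float = 0.2,
    step: float = 0.05,
    pairs: Literal["matched", "all"] = "matched",
) -> list[dict[str, float]]:
    """Cumulative overlap histogram plus MMR as a function of the OS floor.

    For a grid of thresholds x in [min_os, 1], reports the number of pairs
    with OS >= x — either the pairs of the MMR matching at min_os
    (``pairs="matched"``) or all reference x prediction pairs
    (``pairs="all"``) — together with MMR recomputed with floor x.
    Rows are dicts with keys ``threshold``, ``pairs_ge``, ``mmr``.
    """
    if pairs == "matched":
        scores = [os_ for _, _, os_ in mmr_matching(pred, ref, min_os)]
    elif pairs == "all":
        scores = [
            overlap_score(pc, rc)
            for rc in ref
            for pc in pred
            if overlap_score(pc, rc) >= min_os
        ]
    else:
        raise ValueError(f"unknown pairs mode: {pairs!r}")
    grid = np.arange(min_os, 1.0 + 1e-9, step)
    grid[-1] = min(grid[-1], 1.0)
    rows = []
    for x in grid:
        rows.append(
            {
                "threshold": round(float(x), 10),
                "pairs_ge": int(sum(1 for s in scores if s >= x - 1e-12)),
                "mmr": mmr(pred, ref, float(x)) if len(pred) else 0.0,
            }
        )
    return rows


def evaluate(
    pred: ComplexSet,
    ref: ComplexSet,
    config: EvalConfig = EvalConfig(),
    net: PPINetwork | None = None,
) -> EvalReport:
    """Full metric battery; pass *net* to apply reference filtering first."""
    if net is not None:
        ref = filter_reference(ref, net)
    if len(ref) == 0:
        raise ValueError("reference set is empty (after filtering)")
    if len(pred) == 0:
        return EvalReport(
            tp=0, fp=0, fn=len(ref), precision=0.0, recall=0.0, fmeasure=0.0,
            sn=0.0, ppv=0.0, acc=0.0, mmr=0.0, perfect_matches=0,
            n_predicted=0, n_reference=len(ref),
        )
    precision, recall, f, tp, fp, fn = fmeasure_stats(pred, ref, config.match_threshold)
    sn, ppv, acc = accuracy_stats(pred, ref)
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        fmeasure=f,
        sn=sn,
        ppv=ppv,
        acc=acc,
        mmr=mmr(pred, ref, config.mmr_min_os),
        perfect_matches=perfect_match_count(pred, ref),
        n_predicted=len(pred),
        n_reference=len(ref),
    )
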