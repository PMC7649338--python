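"""Object-level (Aggregated Jaccard Index) and pixel-level evaluation.

AJI matches every ground-truth object to the predicted object with maximal
Jaccard index (ties broken toward the lowest predicted label id), sums
matched intersections over matched unions, and adds the pixel mass of
predicted objects that intersect no ground-truth object to the denominator:

    AJI = sum_i |GT_i ∩ PRD*(i)|  /  ( sum_i |GT_i ∪ PRD*(i)| + sum_{l in U} |PRD_l| )

Two variants of the unmatched set U are provided: ``printed`` (the default;
U = predicted objects intersecting no GT object) and ``used_flag`` (U =
predicted objects never selected as a best match, the original AJI
bookkeeping, which additionally penalizes matched-but-unused predictions).

Pixel-level precision, recall and F1 follow the usual confusion-count
definitions; degenerate cases use the conventions: both masks empty -> 1,
exactly one empty -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ShapeError, SizeError
from .imaging import InstanceLabelMap


@dataclass(frozen=True)
class PixelConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "PixelConfusion") -> "PixelConfusion":
        return PixelConfusion(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class SegScores:
    aji: float
    precision: float
    recall: float
    f1: float
    confusion: PixelConfusion


def _check_same_shape(a, b) -> None:
    if tuple(a.shape) != tuple(b.shape):
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")


def _sorted_masks(ilm: InstanceLabelMap) -> list[np.ndarray]:
    return [m for _, m in sorted(ilm.objects, key=lambda o: o[0])]


def aji(gt: InstanceLabelMap, pred: InstanceLabelMap, variant: str = "printed") -> float:
    """Aggregated Jaccard Index between two instance maps."""
    _check_same_shape(np.empty(gt.shape), np.empty(pred.shape))
    if variant not in ("printed", "used_flag"):
        raise ValueError(f"unknown aji variant {variant!r}")
    gt_masks = _sorted_masks(gt)
    pr_masks = _sorted_masks(pred)
    if not gt_masks and not pr_masks:
        return 1.0
    if not gt_masks or not pr_masks:
        return 0.0

    g = np.stack([m.reshape(-1) for m in gt_masks]).astype(np.int64)
    p = np.stack([m.reshape(-1) for m in pr_masks]).astype(np.int64)
    inter = g @ p.T  # (K, L) pairwise intersection counts, exact
    areas_g = g.sum(axis=1)
    areas_p = p.sum(axis=1)
    union = areas_g[:, None] + areas_p[None, :] - inter
    jac = inter / np.maximum(union, 1)

    numer = 0
    denom = 0
    used = np.zeros(len(pr_masks), dtype=bool)
    for i in range(len(gt_masks)):
        j = int(np.argmax(jac[i]))  # argmax takes the first (lowest-id) tie
        if inter[i, j] == 0:
            denom += int(areas_g[i])  # unmatched GT: union with the empty set
            continue
        numer += int(inter[i, j])
        denom += int(union[i, j])
        used[j] = True

    if variant == "printed":
        unmatched = inter.sum(axis=0) == 0
    else:  # used_flag
        unmatched = ~used
    denom += int(areas_p[unmatched].sum())
    return float(numer / denom) if denom > 0 else 1.0


def aji_bruteforce(gt: InstanceLabelMap, pred: InstanceLabelMap, variant: str = "printed") -> float:
    """Set-arithmetic re-derivation of AJI for tiny maps (test oracle)."""
    if len(gt) > 8 or len(pred) > 8:
        raise SizeError("brute-force AJI is limited to <= 8 objects per map")
    _check_same_shape(np.empty(gt.shape), np.empty(pred.shape))
    gt_sets = [
        (lid, frozenset(zip(*np.nonzero(m)))) for lid, m in sorted(gt.objects, key=lambda o: o[0])
    ]
    pr_sets = [
        (lid, frozenset(zip(*np.nonzero(m)))) for lid, m in sorted(pred.objects, key=lambda o: o[0])
    ]
    if not gt_sets and not pr_sets:
        return 1.0
    if not gt_sets or not pr_sets:
        return 0.0
    numer = 0
    denom = 0
    used_ids: set[int] = set()
    intersecting_ids: set[int] = set()
    for _, gset in gt_sets:
        best_j = -1.0
        best = None
        for plid, pset in pr_sets:
            if gset & pset:
                intersecting_ids.add(plid)
            jac = len(gset & pset) / len(gset | pset)
            if jac > best_j:  # strict: first (lowest-id) maximum wins
                best_j, best = jac, (plid, pset)
        if best is None or not (gset & best[1]):
            denom += len(gset)
            continue
        numer += len(gset & best[1])
        denom += len(gset | best[1])
        used_ids.add(best[0])
    keep = intersecting_ids if variant == "printed" else used_ids
    for plid, pset in pr_sets:
        if plid not in keep:
            denom += len(pset)
    return numer / denom if denom > 0 else 1.0


def pixel_scores(gt_mask: np.ndarray, pred_mask: np.ndarray) -> SegScores:
    """Pixel-level precision, recall and F1 between two binary masks."""
    gt_mask = np.asarray(gt_mask).astype(bool)
    pred_mask = np.asarray(pred_mask).astype(bool)
    _check_same_shape(gt_mask, pred_mask)
    tp = int((gt_mask & pred_mask).sum())
    fp = int((~gt_mask & pred_mask).sum())
    fn = int((gt_mask & ~pred_mask).sum())
    tn = int((~gt_mask & ~pred_mask).sum())
    conf = PixelConfusion(tp, fp, fn, tn)
    if not gt_mask.any() and not pred_mask.any():
        return SegScores(float("nan"), 1.0, 1.0, 1.0, conf)
    if not gt_mask.any() or not pred_mask.any():
        return SegScores(float("nan"), 0.0, 0.0, 0.0, conf)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp else 0.0
    return SegScores(float("nan"), precision, recall, f1, conf)


def evaluate_set(pairs, variant: str = "printed") -> SegScores:
    """Unweighted per-image mean of AJI and pixel scores over (gt, pred) pairs.

    ``pairs`` is a nonempty list of ``(gt, pred)`` InstanceLabelMaps; pixel
    scores are computed on the union (semantic) masks; confusion counts are
    summed across images for reporting.
    """
    pairs = list(pairs)
    if not pairs:
        raise DataError("evaluate_set needs at least one (gt, pred) pair")
    ajis, precs, recs, f1s = [], [], [], []
    conf = PixelConfusion(0, 0, 0, 0)
    for gt, pred in pairs:
        ajis.append(aji(gt, pred, variant=variant))
        s = pixel_scores(gt.union_mask(), pred.union_mask())
        precs.append(s.precision)
        recs.append(s.recall)
        f1s.append(s.f1)
        conf = conf + s.confusion
    return SegScores(
        aji=float(np.mean(ajis)),
        precision=float(np.mean(precs)),
        recall=float(np.mean(recs)),
        f1=float(np.mean(f1s)),
        confusion=conf,
    )
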