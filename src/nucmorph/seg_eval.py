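"""Instance-segmentation quality metrics: binary Dice and the Aggregated
Jaccard Index (AJI).

Binary Dice compares the binarized foregrounds and ignores instance
identity; AJI matches each ground-truth instance to at most one predicted
instance and charges every unmatched prediction to the union denominator,
so it additionally penalizes split, merged, and spurious instances.
Matching is greedy per ground-truth instance in ascending id order, each
prediction usable at most once, ties broken toward the lowest prediction
id — a fully deterministic variant of the canonical definition.  Both
metrics are computed in pixel space; physical pixel size plays no role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MatchResult",
    "binary_dice",
    "object_dice",
    "match_instances",
    "aji",
    "evaluate_patchset",
]


@dataclass
class MatchResult:
    """Greedy GT→prediction matching underlying AJI."""

    pairs: list[tuple[int, int, float]]  # (gt_id, pred_id, IoU)
    unmatched_gt: list[int]
    unused_pred: list[int]


def _check_shapes(pred: np.ndarray, gt: np.ndarray) -> None:
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")


def binary_dice(pred_labels: np.ndarray, gt_labels: np.ndarray) -> float:
    """2|P∩G| / (|P|+|G|) on the binarized foregrounds; 1.0 when both are
    empty."""
    _check_shapes(pred_labels, gt_labels)
    p = pred_labels > 0
    g = gt_labels > 0
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def _instance_sizes(labels: np.ndarray) -> dict[int, int]:
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return dict(zip(ids.tolist(), counts.tolist()))


def _overlaps(pred: np.ndarray, gt: np.ndarray) -> dict[int, dict[int, int]]:
    """gt_id -> {pred_id -> intersection pixel count} over co-foreground."""
    both = (pred > 0) & (gt > 0)
    g = gt[both].astype(np.int64)
    p = pred[both].astype(np.int64)
    out: dict[int, dict[int, int]] = {}
    if g.size:
        keys = g * (int(pred.max()) + 1) + p
        uk, counts = np.unique(keys, return_counts=True)
        base = int(pred.max()) + 1
        for k, c in zip(uk.tolist(), counts.tolist()):
            out.setdefault(k // base, {})[k % base] = c
    return out


def match_instances(pred_labels: np.ndarray, gt_labels: np.ndarray) -> MatchResult:
    """Greedy per-GT matching: ascending GT id, pick the unused prediction
    with maximal IoU (ties → lowest pred id); zero-overlap GTs stay
    unmatched."""
    _check_shapes(pred_labels, gt_labels)
    gt_sizes = _instance_sizes(gt_labels)
    pred_sizes = _instance_sizes(pred_labels)
    overlaps = _overlaps(pred_labels, gt_labels)

    used: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    unmatched_gt: list[int] = []
    for gid in sorted(gt_sizes):
        best: tuple[float, int] | None = None  # (-IoU, pred_id) for min()
        for pid, inter in overlaps.get(gid, {}).items():
            if pid in used:
                continue
            iou = inter / (gt_sizes[gid] + pred_sizes[pid] - inter)
            if best is None or (-iou, pid) < best:
                best = (-iou, pid)
        if best is None:
            unmatched_gt.append(gid)
        else:
            iou, pid = -best[0], best[1]
            pairs.append((gid, pid, iou))
            used.add(pid)
    unused_pred = [pid for pid in sorted(pred_sizes) if pid not in used]
    return MatchResult(pairs=pairs, unmatched_gt=unmatched_gt,
                       unused_pred=unused_pred)


def aji(pred_labels: np.ndarray, gt_labels: np.ndarray) -> float:
    """Aggregated Jaccard Index; 1.0 when both maps are empty, 0.0 when
    exactly one is."""
    _check_shapes(pred_labels, gt_labels)
    gt_sizes = _instance_sizes(gt_labels)
    pred_sizes = _instance_sizes(pred_labels)
    if not gt_sizes and not pred_sizes:
        return 1.0
    match = match_instances(pred_labels, gt_labels)
    overlaps = _overlaps(pred_labels, gt_labels)
    inter_total = 0
    union_total = 0
    for gid, pid, _iou in match.pairs:
        inter = overlaps[gid][pid]
        inter_total += inter
        union_total += gt_sizes[gid] + pred_sizes[pid] - inter
    for gid in match.unmatched_gt:
        union_total += gt_sizes[gid]
    for pid in match.unused_pred:
        union_total += pred_sizes[pid]
    return inter_total / union_total if union_total else 0.0


def object_dice(pred_labels: np.ndarray, gt_labels: np.ndarray) -> float:
    """Optional object-level Dice: GT-size-weighted mean of 2I/(|G|+|P|)
    over the greedy matches (unmatched GTs contribute 0)."""
    _check_shapes(pred_labels, gt_labels)
    gt_sizes = _instance_sizes(gt_labels)
    pred_sizes = _instance_sizes(pred_labels)
    if not gt_sizes and not pred_sizes:
        return 1.0
    if not gt_sizes:
        return 0.0
    match = match_instances(pred_labels, gt_labels)
    overlaps = _overlaps(pred_labels, gt_labels)
    total_w = sum(gt_sizes.values())
    acc = 0.0
    for gid, pid, _ in match.pairs:
        inter = overlaps[gid][pid]
        acc += gt_sizes[gid] * (2.0 * inter / (gt_sizes[gid] + pred_sizes[pid]))
    return acc / total_w


def evaluate_patchset(pairs) -> dict:
    """Unweighted mean Dice/AJI across (pred, gt) patch pairs, with the
    per-patch values retained for reporting."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_patchset requires a non-empty list of pairs")
    per_patch = [
        {
            "dice": binary_dice(p, g),
            "aji": aji(p, g),
            "object_dice": object_dice(p, g),
        }
        for p, g in pairs
    ]
    return {
        "mean_dice": float(np.mean([d["dice"] for d in per_patch])),
        "mean_aji": float(np.mean([d["aji"] for d in per_patch])),
        "mean_object_dice": float(np.mean([d["object_dice"] for d in per_patch])),
        "per_patch": per_patch,
    }
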