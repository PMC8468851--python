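"""Aggregate-level and pixel-level comparison of two segmentations.

Aggregates from a reference mask (typically the real fluorescence
segmentation) and a test mask (synthesized or phase-contrast segmentation)
are matched one-to-one by ascending centroid distance; a candidate pair is
accepted only if the two pixel supports overlap and neither aggregate is
more than twice the size of the other.  Pixel-level agreement is summarized
as TP/FP/TN/FN counts with precision = TP/(TP+FP) and recall = TP/(TP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .core import AggregateRecord, SegmentationMask

#: RGB palette for the four-label image: TP white, FP orange, TN black, FN red.
LABEL_COLORS = {
    "TP": (255, 255, 255),
    "FP": (255, 165, 0),
    "TN": (0, 0, 0),
    "FN": (255, 0, 0),
}

#: a matched pair is rejected when max(area)/min(area) exceeds this
AREA_RATIO_LIMIT = 2.0


@dataclass
class MatchResult:
    pairs: list  # (ref_id, test_id, displacement_um, area_ratio)
    ref_unmatched: list
    test_unmatched: list

    def displacements_um(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs], dtype=float)

    def area_ratios(self) -> np.ndarray:
        return np.array([p[3] for p in self.pairs], dtype=float)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def label_aggregates(mask: SegmentationMask) -> list[AggregateRecord]:
    """Extract 8-connected components in raster order of their first pixel."""
    labeled, n = measure.label(mask.values, connectivity=2, return_num=True)
    if n == 0:
        return []
    # raster order of first occurrence
    order: dict[int, int] = {}
    flat = labeled.ravel()
    for lab in flat[flat > 0]:
        if lab not in order:
            order[int(lab)] = len(order)
            if len(order) == n:
                break
    records: list[AggregateRecord] = [None] * n  # type: ignore[list-item]
    px = mask.pixel_size_um
    for lab, idx in order.items():
        ys, xs = np.nonzero(labeled == lab)
        centroid = (float(ys.mean()), float(xs.mean()))
        records[idx] = AggregateRecord(
            id=idx,
            centroid_px=centroid,
            centroid_um=(centroid[1] * px, centroid[0] * px),
            area_px=int(ys.size),
            pixel_set=frozenset(zip(ys.tolist(), xs.tolist())),
        )
    return records


def match_aggregates(
    ref: list[AggregateRecord],
    test: list[AggregateRecord],
    pixel_size_um: float = 1.0,
) -> MatchResult:
    """Greedy one-to-one matching by ascending centroid distance.

    A candidate pair is accepted only if the pixel supports overlap and
    the areas differ by at most a factor of two (in either direction);
    otherwise the pair counts as a mismatch and both aggregates can still
    match other partners.  Ties in distance break toward the lower ref id,
    then the lower test id, making the result independent of input order.
    """
    candidates = []
    for r in ref:
        for t in test:
            d = float(np.hypot(
                r.centroid_px[0] - t.centroid_px[0],
                r.centroid_px[1] - t.centroid_px[1],
            ))
            candidates.append((d, r.id, t.id, r, t))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_ref: set[int] = set()
    used_test: set[int] = set()
    pairs = []
    for d, rid, tid, r, t in candidates:
        if rid in used_ref or tid in used_test:
            continue
        if not (r.pixel_set & t.pixel_set):
            continue
        big, small = max(r.area_px, t.area_px), min(r.area_px, t.area_px)
        if small == 0 or big / small > AREA_RATIO_LIMIT:
            continue
        used_ref.add(rid)
        used_test.add(tid)
        pairs.append((rid, tid, d * pixel_size_um, t.area_px / r.area_px))

    return MatchResult(
        pairs=pairs,
        ref_unmatched=[r.id for r in ref if r.id not in used_ref],
        test_unmatched=[t.id for t in test if t.id not in used_test],
    )


def pixel_confusion(
    ref: SegmentationMask, test: SegmentationMask
) -> tuple[ConfusionCounts, np.ndarray]:
    """Pixel TP/FP/TN/FN tallies plus the four-color label image."""
    if ref.shape != test.shape:
        raise ValueError("masks must have the same shape")
    r, t = ref.values, test.values
    tp = r & t
    fp = ~r & t
    tn = ~r & ~t
    fn = r & ~t
    counts = ConfusionCounts(
        TP=int(tp.sum()), FP=int(fp.sum()), TN=int(tn.sum()), FN=int(fn.sum())
    )
    label = np.zeros((*r.shape, 3), dtype=np.uint8)
    label[tp] = LABEL_COLORS["TP"]
    label[fp] = LABEL_COLORS["FP"]
    label[fn] = LABEL_COLORS["FN"]
    return counts, label


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN when no pixel was called positive."""
    denom = c.TP + c.FP
    return c.TP / denom if denom > 0 else float("nan")


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when the reference has no positive pixel."""
    denom = c.TP + c.FN
    return c.TP / denom if denom > 0 else float("nan")


def summarize(
    ref: SegmentationMask, test: SegmentationMask, pixel_size_um: float | None = None
) -> dict:
    """Movie-frame summary: match statistics plus precision/recall."""
    px = pixel_size_um if pixel_size_um is not None else ref.pixel_size_um
    mres = match_aggregates(
        label_aggregates(ref), label_aggregates(test), pixel_size_um=px
    )
    counts, _ = pixel_confusion(ref, test)
    disp = mres.displacements_um()
    ratio = mres.area_ratios()
    return {
        "n_pairs": len(mres.pairs),
        "n_ref_unmatched": len(mres.ref_unmatched),
        "n_test_unmatched": len(mres.test_unmatched),
        "displacement_um_mean": float(disp.mean()) if disp.size else float("nan"),
        "displacement_um_sd": float(disp.std(ddof=1)) if disp.size > 1 else float("nan"),
        "area_ratio_mean": float(ratio.mean()) if ratio.size else float("nan"),
        "area_ratio_sd": float(ratio.std(ddof=1)) if ratio.size > 1 else float("nan"),
        "precision": precision(counts),
        "recall": recall(counts),
    }
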