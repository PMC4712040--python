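"""Seeded region-growing segmentation of projected epithelium frames.

The stages mirror the classic membrane-marker workflow: register the
projected frames, optionally run CLAHE contrast enhancement, generate
one seed per cell by sweeping a rising intensity threshold, then grow
cellular regions from all seeds simultaneously with a priority-flood
watershed that climbs the membrane intensity gradients.

Determinism contract: the priority flood orders pixels by
(smoothed intensity, insertion counter) — first-come wins — so the label
map is a pure function of the image and the seeds.  Region growth is
4-connected; boundaries are 8-connected.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .params import AnalysisParams

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet", "LabelMap", "register_frames", "enhance_contrast",
    "generate_seeds", "grow_regions", "labelmap_to_skeleton",
]

_CROSS = ndi.generate_binary_structure(2, 1)
_UNVISITED = -1
_BOUNDARY = 0


@dataclass
class SeedSet:
    """Per-frame cell seeds: (seed_id, y, x), ids unique within the frame."""

    seeds: list[tuple[int, float, float]]
    frame_index: int = 0

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.seeds]
        if len(ids) != len(set(ids)):
            raise ValueError("seed ids must be unique within a frame")

    @property
    def is_empty(self) -> bool:
        return len(self.seeds) == 0


@dataclass
class LabelMap:
    """2D integer cell labels; 0 = boundary/background, k > 0 = cell k."""

    labels: np.ndarray
    frame_index: int = 0

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _shift_int(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero fill."""
    out = np.zeros_like(frame)
    h, w = frame.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    yo = slice(max(-dy, 0), min(h - dy, h))
    xo = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = frame[yo, xo]
    return out


def register_frames(frames: list[np.ndarray],
                    max_shift: int | None = None,
                    ) -> tuple[list[tuple[int, int]], list[np.ndarray]]:
    """Chain-register frames by integer-pixel translation.

    Each frame is aligned to the previous *aligned* frame by the integer
    shift maximizing their cross-correlation (phase correlation).  Shifts
    are capped at ``max_shift`` (default: a quarter of the smaller image
    side) so featureless/noise frames cannot drift arbitrarily.
    Out-of-canvas pixels are zero-filled.
    """
    from skimage.registration import phase_cross_correlation

    if not frames:
        raise ValueError("register_frames: no frames")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"register_frames: mixed shapes {sorted(shapes)}")
    if max_shift is None:
        max_shift = min(frames[0].shape) // 4
    offsets = [(0, 0)]
    aligned = [frames[0].copy()]
    for f in frames[1:]:
        shift, _, _ = phase_cross_correlation(
            aligned[-1].astype(np.float64), f.astype(np.float64),
            upsample_factor=1, normalization=None)
        # reported offset = the sample's displacement; the correction
        # applied to align the frame is its negative
        dy = int(np.clip(round(-shift[0]), -max_shift, max_shift))
        dx = int(np.clip(round(-shift[1]), -max_shift, max_shift))
        offsets.append((dy, dx))
        aligned.append(_shift_int(f, -dy, -dx))
    return offsets, aligned


def enhance_contrast(frame: np.ndarray,
                     enhancement_limit: float | None,
                     enhancement_width: float | None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    ``enhancement_limit`` is the clip limit in (0, 1], and
    ``enhancement_width`` the tile size in pixels (>= 8).  Passing
    ``None`` for either (the parameter table's ``#`` skip token) bypasses
    the step.  The output is rescaled to the input's intensity range.
    """
    from skimage import exposure

    if enhancement_limit is None or enhancement_width is None:
        return frame.astype(np.float64, copy=True)
    if not 0 < enhancement_limit <= 1:
        raise ValueError("enhancement_limit must be in (0, 1]")
    if enhancement_width < 8:
        raise ValueError("enhancement_width must be >= 8 pixels")
    f = frame.astype(np.float64)
    lo, hi = float(f.min()), float(f.max())
    if hi == lo:
        return f
    norm = (f - lo) / (hi - lo)
    eq = exposure.equalize_adapthist(
        norm, kernel_size=int(enhancement_width),
        clip_limit=float(enhancement_limit))
    return eq * (hi - lo) + lo


def generate_seeds(frame: np.ndarray, params: AnalysisParams,
                   level_step: float = 1.0) -> SeedSet:
    """One seed per cell by a rising-threshold region sweep.

    The frame is Gaussian-smoothed with ``sigma1``; an intensity
    threshold then rises from ``params.threshold`` in ``level_step``
    increments.  At each level, connected components of the sub-threshold
    mask that contain no existing region and have area >=
    ``min_cell_size`` become new embryonic regions; components containing
    exactly one existing region extend it; components spanning several
    regions leave them untouched (the separating ridge is preserved).
    Finally, adjacent embryonic regions separated by a weak ridge —
    (mean ridge intensity - min interior mean) / global ridge max <
    ``merge_criteria`` — are fused, and each final region contributes one
    seed at its centroid.

    A zero-seed outcome is returned flagged (``is_empty``), not raised.
    """
    from skimage.segmentation import watershed

    g = ndi.gaussian_filter(frame.astype(np.float64), params.sigma1)
    regions = np.zeros(frame.shape, dtype=np.int32)
    next_id = 1
    levels = np.arange(params.threshold, 255.0 + level_step, level_step)
    for thr in levels:
        mask = g < thr
        if not mask.any():
            continue
        comp, n = ndi.label(mask, structure=_CROSS)
        if n == 0:
            continue
        # how many distinct regions does each component contain?
        claimed = regions > 0
        pair_comp = comp[claimed]
        pair_reg = regions[claimed]
        mapping = np.zeros(n + 1, dtype=np.int64)   # comp -> region to fill
        if pair_comp.size:
            uniq = np.unique(np.stack([pair_comp, pair_reg]), axis=1)
            counts = np.bincount(uniq[0], minlength=n + 1)
            single = counts == 1
            first_reg = np.zeros(n + 1, dtype=np.int64)
            first_reg[uniq[0][::-1]] = uniq[1][::-1]
            mapping[single] = first_reg[single]
            multi = counts >= 2
        else:
            multi = np.zeros(n + 1, dtype=bool)
        # new regions: components with no claimed pixel and enough area
        areas = np.bincount(comp.ravel(), minlength=n + 1)
        has_region = np.zeros(n + 1, dtype=bool)
        if pair_comp.size:
            has_region[np.unique(pair_comp)] = True
        for c in np.nonzero(~has_region & (areas >= params.min_cell_size))[0]:
            if c == 0:
                continue
            mapping[c] = next_id
            next_id += 1
        mapping[multi] = 0
        fill = mapping[comp]
        write = mask & (fill > 0) & (regions == 0)
        regions[write] = fill[write]
    if next_id == 1:
        return SeedSet(seeds=[], frame_index=0)
    # weak-ridge merging between adjacent embryonic regions
    basins = watershed(g, markers=regions, watershed_line=True)
    line = basins == 0
    parent = list(range(next_id))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    ridge_vals: dict[tuple[int, int], list[float]] = {}
    ly, lx = np.nonzero(line)
    h, w = g.shape
    for y, x in zip(ly.tolist(), lx.tolist()):
        labs = set()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and basins[yy, xx] > 0:
                labs.add(int(basins[yy, xx]))
        for a in labs:
            for b in labs:
                if a < b:
                    ridge_vals.setdefault((a, b), []).append(g[y, x])
    if ridge_vals:
        ridge_max = max(max(v) for v in ridge_vals.values())
        means = ndi.labeled_comprehension(
            g, regions, np.arange(1, next_id), np.mean, float, np.nan)
        interior_mean = {i + 1: m for i, m in enumerate(means)}
        for (a, b), vals in sorted(ridge_vals.items(),
                                   key=lambda kv: np.mean(kv[1])):
            lo = min(interior_mean.get(a, np.inf), interior_mean.get(b, np.inf))
            score = (float(np.mean(vals)) - lo) / ridge_max if ridge_max > 0 else 0.0
            if score < params.merge_criteria:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for rid in range(1, next_id):
        groups.setdefault(find(rid), []).append(rid)
    seeds = []
    for sid, (root, members) in enumerate(sorted(groups.items()), start=1):
        mask = np.isin(regions, members)
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean(), xs.mean()
        # snap the seed to the nearest pixel of its own region
        k = np.argmin((ys - cy) ** 2 + (xs - cx) ** 2)
        seeds.append((sid, float(ys[k]), float(xs[k])))
    return SeedSet(seeds=seeds, frame_index=0)


def priority_flood(g: np.ndarray, seeds: list[tuple[int, int, int]],
                   ) -> np.ndarray:
    """Priority-flood watershed on image ``g`` from labelled seeds.

    Seeds are (label, y, x).  Pixels are assimilated in ascending
    (intensity, insertion counter) order, 4-connected; a pixel reached
    while already flanked by a different region becomes boundary (0).
    Returns an int32 label image (-1 never remains).
    """
    h, w = g.shape
    labels = np.full((h, w), _UNVISITED, dtype=np.int32)
    heap: list[tuple[float, int, int, int, int]] = []
    counter = 0
    # markers are assigned up front (a region always contains its seed)
    for lab, y, x in seeds:
        if not (0 <= y < h and 0 <= x < w):
            raise ValueError(f"seed ({y},{x}) outside image")
        labels[y, x] = lab
    for lab, y, x in seeds:
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and labels[yy, xx] == _UNVISITED:
                heapq.heappush(heap, (float(g[yy, xx]), counter, yy, xx, lab))
                counter += 1
    while heap:
        val, _, y, x, lab = heapq.heappop(heap)
        if labels[y, x] != _UNVISITED:
            continue
        contested = False
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and labels[yy, xx] > 0 \
                    and labels[yy, xx] != lab:
                contested = True
                break
        if contested:
            labels[y, x] = _BOUNDARY
            continue
        labels[y, x] = lab
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and labels[yy, xx] == _UNVISITED:
                heapq.heappush(heap, (float(g[yy, xx]), counter, yy, xx, lab))
                counter += 1
    labels[labels == _UNVISITED] = _BOUNDARY
    return labels


def grow_regions(frame: np.ndarray, seeds: SeedSet,
                 params: AnalysisParams) -> LabelMap:
    """Grow cellular regions from seeds by priority flood.

    The flood runs on the ``sigma3``-smoothed frame.  Post-passes: (1)
    boundary segments whose mean intensity on the raw frame is below
    ``i_bound_max`` fuse their flanking regions, processed once in
    ascending boundary-intensity order; (2) regions larger than
    ``large_cell_size_thres`` are relabelled background (logged).
    """
    if seeds.is_empty:
        raise ValueError("grow_regions requires at least one seed")
    g = ndi.gaussian_filter(frame.astype(np.float64), params.sigma3)
    seed_px = [(sid, int(round(y)), int(round(x)))
               for sid, y, x in seeds.seeds]
    labels = priority_flood(g, seed_px)
    labels = _merge_weak_boundaries(labels, frame.astype(np.float64),
                                    params.i_bound_max)
    # exclude oversized regions (merged backgrounds, image margins ...)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    for rid, n in zip(ids, counts):
        if n > params.large_cell_size_thres:
            logger.info("grow_regions: region %d (area %d) exceeds "
                        "large_cell_size_thres; relabelled background", rid, n)
            labels[labels == rid] = _BOUNDARY
    return LabelMap(labels=labels, frame_index=seeds.frame_index)


def _merge_weak_boundaries(labels: np.ndarray, frame: np.ndarray,
                           i_bound_max: float) -> np.ndarray:
    """Single ascending-intensity pass fusing weakly separated regions."""
    h, w = labels.shape
    by, bx = np.nonzero(labels == _BOUNDARY)
    seg_vals: dict[tuple[int, int], list[float]] = {}
    seg_px: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for y, x in zip(by.tolist(), bx.tolist()):
        labs = set()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and labels[yy, xx] > 0:
                    labs.add(int(labels[yy, xx]))
        for a in labs:
            for b in labs:
                if a < b:
                    seg_vals.setdefault((a, b), []).append(frame[y, x])
                    seg_px.setdefault((a, b), []).append((y, x))
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent.setdefault(parent[a], parent[a])
            a = parent[a]
        return a

    merged_pairs = []
    for (a, b), vals in sorted(seg_vals.items(), key=lambda kv: np.mean(kv[1])):
        if float(np.mean(vals)) < i_bound_max:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
                merged_pairs.append((a, b))
    if not parent:
        return labels
    out = labels.copy()
    max_lab = int(labels.max())
    lut = np.arange(max_lab + 1, dtype=np.int32)
    for lab in range(1, max_lab + 1):
        lut[lab] = find(lab)
    out[out > 0] = lut[out[out > 0]]
    # absorb the now-internal boundary pixels of merged pairs
    for a, b in merged_pairs:
        ra = lut[a]
        for y, x in seg_px[(a, b)]:
            if out[y, x] == _BOUNDARY:
                out[y, x] = ra
    return out


def labelmap_to_skeleton(m: LabelMap):
    """1-pixel-wide boundary skeleton of a label map.

    Foreground = the label-0 boundary pixels, plus a one-sided marking of
    direct transitions between different positive labels, so faces stay
    4-connected and closed with exactly one face per region.
    """
    from .io import Skeleton

    lab = m.labels
    skel = lab == _BOUNDARY
    # one-sided axis marks: the resulting line is 8-connected along any
    # boundary staircase, which suffices to separate 4-connected faces
    down = np.zeros_like(skel)
    down[:-1, :] = (lab[:-1, :] != lab[1:, :]) & (lab[:-1, :] > 0) & (lab[1:, :] > 0)
    right = np.zeros_like(skel)
    right[:, :-1] = (lab[:, :-1] != lab[:, 1:]) & (lab[:, :-1] > 0) & (lab[:, 1:] > 0)
    skel = skel | down | right
    return Skeleton(skel.astype(np.uint8), frame_index=m.frame_index)
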