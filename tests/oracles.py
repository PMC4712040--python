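"""Independent reference implementations used only to check the package.

These deliberately avoid the production code paths: the flood oracle
selects its next pixel by a linear scan instead of a heap, and the
neighbor-count oracle works on the generator's Voronoi-ridge adjacency
instead of the package's polygon-intersection graph.
"""

from __future__ import annotations

import numpy as np


def priority_flood_bruteforce(g: np.ndarray,
                              seeds: list[tuple[int, int, int]]) -> np.ndarray:
    """Exhaustive priority flood: same (intensity, insertion counter)
    ordering and contested-pixel rule as the production watershed, but
    the minimum is found by scanning an open list."""
    h, w = g.shape
    labels = np.full((h, w), -1, dtype=np.int32)
    open_list: list[tuple[float, int, int, int, int]] = []
    counter = 0
    for lab, y, x in seeds:
        labels[y, x] = lab
    for lab, y, x in seeds:
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and labels[yy, xx] == -1:
                open_list.append((float(g[yy, xx]), counter, yy, xx, lab))
                counter += 1
    while open_list:
        k = 0
        for i in range(1, len(open_list)):
            if open_list[i][:2] < open_list[k][:2]:
                k = i
        val, _, y, x, lab = open_list.pop(k)
        if labels[y, x] != -1:
            continue
        contested = False
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and labels[yy, xx] > 0 \
                    and labels[yy, xx] != lab:
                contested = True
                break
        if contested:
            labels[y, x] = 0
            continue
        labels[y, x] = lab
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and labels[yy, xx] == -1:
                open_list.append((float(g[yy, xx]), counter, yy, xx, lab))
                counter += 1
    labels[labels == -1] = 0
    return labels


def neighbor_distribution_from_ridges(tissue, frame: int,
                                      min_length: float = 1.0):
    """Polygon-class frequencies of interior cells straight from the
    generator's Voronoi ridge lengths (no shapely involved)."""
    fr = tissue.frames[frame]
    interior = set(tissue.interior_ids(frame, margin=1e-6))
    deg = {i: 0 for i in fr.polygons}
    for key, length in fr.adjacency.items():
        if length >= min_length:
            for c in key:
                deg[c] += 1
    counts: dict[int, int] = {}
    for i in interior:
        counts[deg[i]] = counts.get(deg[i], 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}
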