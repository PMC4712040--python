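"""Shared fixtures: synthetic tissues, rendered stacks, linked graphs.

Heavy fixtures are session-scoped so the whole suite pays for each
simulation once.
"""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Polygon

from epigraph.graph import build_frame_graph, cells_from_polygons, link_frames
from epigraph.synthetic import GroundTruthTissue, RenderSpec, generate_tissue, render_stack


def build_linked(tissue: GroundTruthTissue):
    """Link a ground-truth tissue through the package's own graph path."""
    fgs = [build_frame_graph(cells_from_polygons(fr.polygons, fr.index,
                                                 box=tissue.box))
           for fr in tissue.frames]
    return link_frames(fgs, frame_interval=tissue.frame_interval)


def honeycomb(n_rings: int = 2, r: float = 10.0) -> dict[int, Polygon]:
    """Regular hexagon tiling: center cell plus ``n_rings`` rings."""
    centers = []
    for q in range(-n_rings, n_rings + 1):
        for s in range(-n_rings, n_rings + 1):
            if abs(q + s) <= n_rings:
                x = r * np.sqrt(3) * (q + s / 2)
                y = r * 1.5 * s
                centers.append((x, y))
    th = np.pi / 2 + np.arange(6) * np.pi / 3
    out = {}
    for i, (cx, cy) in enumerate(centers):
        out[i] = Polygon(np.column_stack([cx + r * np.cos(th),
                                          cy + r * np.sin(th)]))
    return out


@pytest.fixture(scope="session")
def dome_render():
    """Small dome-shaped monolayer with a decoy layer 5 slices above."""
    tissue = generate_tissue(20, 2, rng_seed=7, jitter=0.05)
    spec = RenderSpec(n_z=24, z_base=6.0, dome_amplitude=8.0,
                      decoy_offset=5.0, noise_sigma=5.0,
                      gradient_amplitude=0.3)
    return tissue, spec, render_stack(tissue, spec)


@pytest.fixture(scope="session")
def seg_render():
    """~200-cell flat noisy rendering for segmentation accuracy checks."""
    tissue = generate_tissue(200, 1, rng_seed=9)
    spec = RenderSpec(n_z=1, noise_sigma=6.0, gradient_amplitude=0.3,
                      membrane_intensity=200.0, interior_intensity=12.0,
                      background=0.0)
    return tissue, render_stack(tissue, spec)


@pytest.fixture(scope="session")
def events_tissue():
    """Clean fixture with scripted divisions and eliminations."""
    return generate_tissue(
        250, 20, rng_seed=21, jitter=0.05,
        divisions=[{"frame": 5, "angle": 30.0}, {"frame": 9, "angle": 120.0},
                   {"frame": 14, "angle": 75.0}],
        eliminations=[{"frame": 4}, {"frame": 11}])


@pytest.fixture(scope="session")
def events_graph(events_tissue):
    return build_linked(events_tissue)


@pytest.fixture(scope="session")
def t1_suite():
    """Three clean tissues, nine scripted T1s each (3 per dynamics class)."""
    out = []
    for seed in (11, 12, 13):
        script = [{"frame": 2 + 3 * i, "template": tpl}
                  for i, tpl in enumerate(["fast", "slow", "transient"] * 3)]
        tissue = generate_tissue(260, 36, rng_seed=seed, t1s=script,
                                 jitter=0.05)
        out.append((tissue, build_linked(tissue)))
    return out


@pytest.fixture(scope="session")
def big_tessellation():
    """1,000-cell relaxed tessellation (single frame)."""
    tissue = generate_tissue(1000, 1, rng_seed=5)
    from epigraph.graph import SpatioTemporalGraph
    fg = build_frame_graph(cells_from_polygons(
        tissue.frames[0].polygons, 0, box=tissue.box))
    return tissue, SpatioTemporalGraph([fg])
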