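"""Quantitative read-outs from the spatiotemporal cell graph.

Polygon-class statistics, cell geometry (area / best-fit-ellipse
elongation / orientation), population classes (daughter, dividing,
eliminated, stable), division orientation, T1 (intercalation) detection
and fast/slow/transient classification, and junction length/intensity
tracks.

Angle conventions: all orientations are undirected axes in image
coordinates, reported in degrees in [0, 180); orientation *differences*
are folded to [0, 90].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .graph import (CellNode, Division, Elimination, SpatioTemporalGraph)

__all__ = [
    "polygon_distribution", "cell_geometry", "classify_populations",
    "division_orientation", "DivisionOrientation", "detect_t1",
    "classify_t1", "junction_series", "t1_rate", "T1Event", "JunctionTrack",
    "InsufficientObservationError",
]

#: default cut for "significantly elongated" cells (major/minor axis)
ELONGATION_THRESHOLD = 1.3


class InsufficientObservationError(ValueError):
    """An event cannot be measured within the observation window."""


# ---------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------

def _polygon_moments(coords: np.ndarray) -> tuple[float, float, float, float]:
    """Area and second central moments (mu_xx, mu_yy, mu_xy, per unit
    area) of a simple closed polygon, by the shoelace-type integrals."""
    x, y = coords[:, 0], coords[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        raise ValueError("degenerate polygon (zero area)")
    cx = ((x + x1) * cross).sum() / (6 * a)
    cy = ((y + y1) * cross).sum() / (6 * a)
    ixx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    iyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    mu_xx = ixx / a - cx * cx
    mu_yy = iyy / a - cy * cy
    mu_xy = ixy / a - cx * cy
    if a < 0:
        a, mu_xx, mu_yy, mu_xy = -a, -mu_xx, -mu_yy, -mu_xy
    return float(a), float(mu_xx), float(mu_yy), float(mu_xy)


def cell_geometry(node: CellNode) -> tuple[float, float, float]:
    """(area, elongation_ratio, major_axis_angle_deg) of a cell.

    Area by the shoelace rule; the best-fit ellipse comes from the second
    central moments of the polygon region; the major-axis angle is in
    [0, 180) degrees (image coordinates, measured from the +x axis).
    """
    coords = np.asarray(node.polygon.exterior.coords)[:-1]
    a, mu_xx, mu_yy, mu_xy = _polygon_moments(coords)
    # eigenvalues of the covariance matrix
    tr = mu_xx + mu_yy
    det = mu_xx * mu_yy - mu_xy ** 2
    disc = max(0.0, (tr / 2) ** 2 - det)
    lam1 = tr / 2 + np.sqrt(disc)
    lam2 = tr / 2 - np.sqrt(disc)
    ratio = float(np.sqrt(lam1 / lam2)) if lam2 > 0 else np.inf
    angle = float(np.rad2deg(0.5 * np.arctan2(2 * mu_xy, mu_xx - mu_yy))) % 180.0
    return a, ratio, angle


def fold_angle_difference(a_deg: float, b_deg: float) -> float:
    """Unsigned difference between two undirected axes, in [0, 90]."""
    d = abs(a_deg - b_deg) % 180.0
    return min(d, 180.0 - d)


# ---------------------------------------------------------------------
# polygon classes and populations
# ---------------------------------------------------------------------

def polygon_distribution(graph: SpatioTemporalGraph, frame: int
                         ) -> dict[int, float]:
    """Frequency of polygon classes (neighbor counts) at one frame.

    Border cells are excluded from the distribution (their neighbor
    count is censored by the field of view) but still count as neighbors
    of interior cells.  An empty frame yields an empty dict.
    """
    fg = graph.frames[frame]
    counts: dict[int, int] = {}
    total = 0
    for cid, cell in fg.cells.items():
        if cell.on_border:
            continue
        k = graph.degree_spatial(frame, cid)
        counts[k] = counts.get(k, 0) + 1
        total += 1
    if total == 0:
        return {}
    return {k: v / total for k, v in sorted(counts.items())}


def classify_populations(graph: SpatioTemporalGraph,
                         min_observation: int = 10
                         ) -> dict[tuple[int, int], str]:
    """Label each cell track: daughter / dividing / eliminated / stable.

    A track is keyed by its first (frame, cell_id).  Tracks observed for
    fewer than ``min_observation`` frames are excluded.  Terminal events
    take precedence over origin: a daughter that later divides is
    labelled ``dividing``.
    """
    mothers = set()
    daughters = set()
    eliminated = set()
    for e in graph.events:
        if isinstance(e, Division):
            mothers.add(e.mother)
            daughters.update(e.daughters)
        elif isinstance(e, Elimination):
            eliminated.add(e.cell)
    labels: dict[tuple[int, int], str] = {}
    seen: set[tuple[int, int]] = set()
    for node in graph.nodes():
        root = graph.track_root(*node)
        if root in seen:
            continue
        seen.add(root)
        chain = graph.track_of(*root)
        if len(chain) < min_observation:
            continue
        tail = chain[-1]
        if tail in mothers:
            labels[root] = "dividing"
        elif tail in eliminated:
            labels[root] = "eliminated"
        elif root in daughters:
            labels[root] = "daughter"
        else:
            labels[root] = "stable"
    return labels


# ---------------------------------------------------------------------
# division orientation
# ---------------------------------------------------------------------

@dataclass
class DivisionOrientation:
    angle_deg: float          # mean folded angle, in [0, 90]
    n_combinations: int       # pre x post frame pairs averaged
    mother_axis_angles: list[float]
    junction_angles: list[float]


def division_orientation(event: Division, graph: SpatioTemporalGraph,
                         frame_interval: float | None = None,
                         pre_window_minutes: Sequence[float] = (72, 66, 60, 54, 48),
                         n_post: int = 5) -> DivisionOrientation:
    """Angle between the mother's long axis and the daughters' new junction.

    The mother's long axis is measured at the time points
    ``pre_window_minutes`` before the division (daughters first visible),
    skipping the immediately pre-mitotic frames where apical rounding
    makes the axis unreliable.  The new junction's angle is measured in
    each of the first ``n_post`` post-division frames as the
    perpendicular to the daughter centroid-centroid segment.  The result
    is the mean over all (pre, post) combinations of the angle
    difference folded to [0, 90] degrees.

    Raises :class:`InsufficientObservationError` when the mother or the
    daughters are not observed long enough.
    """
    if frame_interval is None:
        frame_interval = graph.frame_interval
    f_div = event.frame
    offsets = sorted({int(round(m / frame_interval)) for m in pre_window_minutes},
                     reverse=True)
    # walk the mother's identity chain backwards from its last appearance
    chain = {}
    node = event.mother
    chain[node[0]] = node
    while node in graph.predecessors:
        pred = graph.predecessors[node]
        if len(graph.successors.get(pred, [])) != 1:
            break
        node = pred
        chain[node[0]] = node
    axis_angles = []
    for off in offsets:
        f = f_div - off
        if f not in chain:
            raise InsufficientObservationError(
                f"mother not observed {off} frames before division")
        _, _, angle = cell_geometry(graph.cell(*chain[f]))
        axis_angles.append(angle)
    (d1, d2) = event.daughters
    junction_angles = []
    for k in range(n_post):
        f = f_div + k
        n1 = _follow(graph, d1, f)
        n2 = _follow(graph, d2, f)
        if n1 is None or n2 is None:
            raise InsufficientObservationError(
                f"daughters not observed {k} frames after division")
        c1 = graph.cell(*n1).centroid
        c2 = graph.cell(*n2).centroid
        seg = np.rad2deg(np.arctan2(c2[0] - c1[0], c2[1] - c1[1])) % 180.0
        junction_angles.append((seg + 90.0) % 180.0)
    diffs = [fold_angle_difference(a, j)
             for a in axis_angles for j in junction_angles]
    return DivisionOrientation(
        angle_deg=float(np.mean(diffs)),
        n_combinations=len(diffs),
        mother_axis_angles=axis_angles,
        junction_angles=junction_angles)


def _follow(graph: SpatioTemporalGraph, node: tuple[int, int],
            frame: int) -> tuple[int, int] | None:
    """Follow a cell's identity chain forward to *frame* (or None)."""
    while node[0] < frame:
        succ = graph.successors.get(node, [])
        if len(succ) != 1:
            return None
        node = succ[0]
    return node if node[0] == frame and node[1] in graph.frames[frame].cells \
        else None


# ---------------------------------------------------------------------
# T1 transitions
# ---------------------------------------------------------------------

@dataclass
class T1Event:
    """A neighbor exchange among a quartet of cells.

    ``losers`` are the pair whose junction shrinks away, ``winners`` the
    pair gaining the new junction.  ``junction_length_series`` holds per
    frame the signed junction length: positive while the losers are
    adjacent (old junction), negative of the winners' junction length
    once they are (new junction), 0 at the fourfold vertex.
    """

    frame_of_exchange: int
    losers: tuple[tuple[int, int], tuple[int, int]]    # track roots
    winners: tuple[tuple[int, int], tuple[int, int]]
    junction_length_series: list[float]
    frames: list[int]
    t1_class: str | None = None


def _track_maps(graph: SpatioTemporalGraph):
    """Per frame: cell_id -> track root, and track root -> cell_id."""
    to_root = []
    from_root = []
    for fg in graph.frames:
        fwd = {}
        rev = {}
        for cid in fg.cells:
            root = graph.track_root(fg.frame, cid)
            fwd[cid] = root
            rev[root] = cid
        to_root.append(fwd)
        from_root.append(rev)
    return to_root, from_root


def detect_t1(graph: SpatioTemporalGraph,
              min_junction: float = 2.5) -> list[T1Event]:
    """Detect neighbor-exchange (T1/intercalation) events.

    For every tracked cell pair that loses adjacency while a previously
    non-adjacent pair of their common neighbors gains it, a
    :class:`T1Event` is emitted with the full signed junction-length
    series.  Repeated flips of the same quartet (including fourfold
    vertices lasting several frames) merge into one ongoing event.
    Exchanges where neither configuration's junction ever reaches
    ``min_junction`` px are discarded as segmentation flicker; divisions
    do not qualify because a daughter's track does not span the exchange.
    """
    if graph.n_frames < 3:
        raise ValueError("detect_t1 needs >= 3 linked frames")
    to_root, from_root = _track_maps(graph)
    adj_by_frame: list[set[frozenset]] = []
    len_by_frame: list[dict[frozenset, float]] = []
    for t, fg in enumerate(graph.frames):
        adj = set()
        lens = {}
        for a, b, data in fg.adjacency.edges(data=True):
            key = frozenset((to_root[t][a], to_root[t][b]))
            adj.add(key)
            lens[key] = float(data.get("length", 0.0))
        adj_by_frame.append(adj)
        len_by_frame.append(lens)
    nbrs_by_frame: list[dict] = []
    for adj in adj_by_frame:
        nbrs: dict = {}
        for k in adj:
            a, b = tuple(k)
            nbrs.setdefault(a, set()).add(b)
            nbrs.setdefault(b, set()).add(a)
        nbrs_by_frame.append(nbrs)
    # candidate quartets, anchored on the loss of the old junction; the
    # new junction may only appear after a multi-frame fourfold vertex
    quartets: dict[frozenset, dict] = {}
    for t in range(graph.n_frames - 1):
        both = set(to_root[t].values()) & set(to_root[t + 1].values())
        lost = {k for k in adj_by_frame[t] - adj_by_frame[t + 1]
                if all(r in both for r in k)}
        for l_key in lost:
            a, b = tuple(l_key)
            common = (nbrs_by_frame[t].get(a, set())
                      & nbrs_by_frame[t].get(b, set())) & both
            for c in common:
                for d in common:
                    if not (c < d) or frozenset((c, d)) in adj_by_frame[t]:
                        continue
                    quartets.setdefault(l_key | {c, d}, {
                        "losers": (a, b), "winners": (c, d)})
    events = []
    for quartet, rec in quartets.items():
        losers = rec["losers"]
        winners = rec["winners"]
        l_key, w_key = frozenset(losers), frozenset(winners)
        series, frames = [], []
        for t in range(graph.n_frames):
            if not quartet <= set(to_root[t].values()):
                continue
            frames.append(t)
            if l_key in len_by_frame[t]:
                series.append(len_by_frame[t][l_key])
            elif w_key in len_by_frame[t]:
                series.append(-len_by_frame[t][w_key])
            else:
                series.append(0.0)
        arr = np.asarray(series)
        # the exchange must complete: the old junction was real and the
        # new one actually grows (filters out segmentation flicker)
        if arr.size == 0 or arr.max() < min_junction or arr.min() > -min_junction:
            continue
        exchange_idx = int(np.nonzero(arr < 0)[0][0])
        events.append(T1Event(
            frame_of_exchange=frames[exchange_idx], losers=losers,
            winners=winners, junction_length_series=series, frames=frames))
    events.sort(key=lambda e: e.frame_of_exchange)
    return events


def classify_t1(e: T1Event, observation_end: int | None = None,
                eps: float = 1.0, k_fast: int = 2) -> str:
    """Classify a T1 event as fast, slow, transient or censored.

    * ``transient``: the exchange reverses (the old configuration
      returns) at least once after first completing;
    * ``fast``: no reversal and at most ``k_fast`` frames within ``eps``
      of zero length in the contiguous run around the exchange — the
      cells exchange neighbors decisively and stay exchanged;
    * ``slow``: no reversal but a longer dwell near the fourfold vertex;
    * ``censored``: the exchange never completes inside the observation
      window.
    """
    s = np.asarray(e.junction_length_series, dtype=float)
    if observation_end is not None:
        keep = [i for i, f in enumerate(e.frames) if f <= observation_end]
        s = s[keep]
    neg = np.nonzero(s <= -eps)[0]
    if neg.size == 0:
        cls = "censored"
    else:
        first = neg[0]
        if (s[first:] > eps).any():
            cls = "transient"
        else:
            near = np.abs(s) <= eps
            # contiguous near-zero run ending at the completion frame
            run = 0
            i = first - 1
            while i >= 0 and near[i]:
                run += 1
                i -= 1
            j = first
            while j < len(s) and near[j]:
                run += 1
                j += 1
            cls = "fast" if run <= k_fast else "slow"
    e.t1_class = cls
    return cls


@dataclass
class JunctionTrack:
    """Length and mean boundary intensity of one junction over time."""

    pair: tuple[tuple[int, int], tuple[int, int]]   # track roots
    frames: list[int]
    lengths: list[float]
    intensities: list[float]

    @property
    def is_empty(self) -> bool:
        return len(self.frames) == 0


def junction_series(graph: SpatioTemporalGraph,
                    pair: tuple[tuple[int, int], tuple[int, int]]
                    ) -> JunctionTrack:
    """Per-frame shared-junction length and mean underlying intensity.

    ``pair`` is a pair of track roots (first (frame, cell_id) of each
    cell).  Frames where the cells are not adjacent are omitted; a
    never-adjacent pair yields an empty (flagged) track.  Intensity is
    sampled from each frame graph's attached image along the wall pixels
    (or the shared line for polygon-derived cells); NaN without an image.
    """
    to_root, from_root = _track_maps(graph)
    ra, rb = pair
    frames, lengths, intens = [], [], []
    for t, fg in enumerate(graph.frames):
        ca = from_root[t].get(ra)
        cb = from_root[t].get(rb)
        if ca is None or cb is None or not fg.adjacency.has_edge(ca, cb):
            continue
        data = fg.adjacency.edges[ca, cb]
        frames.append(t)
        lengths.append(float(data.get("length", 0.0)))
        intens.append(_wall_intensity(fg, data))
    return JunctionTrack(pair=pair, frames=frames, lengths=lengths,
                         intensities=intens)


def _wall_intensity(fg, edge_data) -> float:
    if fg.image is None:
        return float("nan")
    if "pixels" in edge_data:
        px = edge_data["pixels"]
        return float(np.mean(fg.image[px[:, 0], px[:, 1]]))
    geom = edge_data.get("geometry")
    if geom is None or geom.is_empty or geom.length == 0:
        return float("nan")
    from scipy import ndimage as ndi
    n = max(2, int(np.ceil(geom.length)))
    line = geom if geom.geom_type == "LineString" else geom.boundary
    try:
        samples = [line.interpolate(d) for d in np.linspace(0, line.length, n)]
    except Exception:
        return float("nan")
    ys = [p.y for p in samples]
    xs = [p.x for p in samples]
    vals = ndi.map_coordinates(fg.image.astype(float), [ys, xs], order=1)
    return float(np.mean(vals))


def t1_rate(events: Sequence[T1Event], graph: SpatioTemporalGraph,
            frame_interval: float | None = None) -> float:
    """Intercalation rate in transitions per 1,000 cells per hour."""
    if frame_interval is None:
        frame_interval = graph.frame_interval
    hours = (graph.n_frames - 1) * frame_interval / 60.0
    if hours <= 0:
        raise ValueError("t1_rate: zero observation duration")
    interior_counts = [
        sum(1 for c in fg.cells.values() if not c.on_border)
        for fg in graph.frames]
    mean_cells = float(np.mean(interior_counts))
    if mean_cells == 0:
        raise ValueError("t1_rate: no interior cells")
    return len(events) / (mean_cells / 1000.0) / hours
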