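"""Spatiotemporal cell graph: geometry extraction, adjacency, temporal linking.

Cells are polygonal faces of a boundary skeleton (or of a ground-truth
tessellation).  Within a frame, two cells are adjacent iff they share a
boundary segment of length >= 1 px; point contact at a vertex is not
adjacency.  Across frames, cells are linked by identity matching; cells
that appear or vanish without a match are explained by division,
elimination, border crossing, or flagged as segmentation-error candidates.

Conventions: pixel coordinates are 0-based (row=y, col=x); shapely
polygons are stored in (x, y) axis order; ``CellNode.centroid`` is (y, x).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import networkx as nx
import numpy as np
import shapely
from scipy import ndimage as ndi
from shapely.geometry import Polygon

from .io import Skeleton
from .segmentation import SeedSet

logger = logging.getLogger(__name__)

__all__ = [
    "CellNode", "FrameGraph", "SpatioTemporalGraph",
    "Division", "Elimination", "ErrorCandidate", "SeedTrack",
    "track_seeds", "apply_seed_edits", "extract_cells", "cells_from_polygons",
    "build_frame_graph", "link_frames", "edit_skeleton",
]

_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class CellNode:
    """One cell in one frame.

    ``polygon`` is the closed face outline (shapely, (x, y) order);
    ``area`` is its shoelace area; ``walls`` optionally holds pixel-level
    adjacency extracted from a label image (neighbor cell id ->
    (wall length in px, wall pixel coordinates)).
    """

    frame: int
    cell_id: int
    polygon: Polygon
    centroid: tuple[float, float]  # (y, x)
    area: float
    on_border: bool
    walls: dict[int, tuple[float, np.ndarray]] | None = None


@dataclass
class SeedTrack:
    track_id: int
    members: list[tuple[int, int]]  # (frame, seed_id), frame-ordered
    status: Literal["continuous", "broken"]
    break_frame: int | None = None


@dataclass(frozen=True)
class Division:
    frame: int          # frame where the daughters are first visible
    mother: tuple[int, int]       # (frame, cell_id) of last mother appearance
    daughters: tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class Elimination:
    frame: int          # last frame the cell is visible
    cell: tuple[int, int]


@dataclass(frozen=True)
class ErrorCandidate:
    frame: int
    cell: tuple[int, int]
    reason: str


@dataclass
class FrameGraph:
    """Cells of one frame plus their spatial adjacency.

    ``adjacency`` is an undirected graph on cell ids with edge attributes
    ``length`` (shared-junction length, px) and optionally ``pixels``
    (wall pixel coordinates) or ``geometry`` (shapely line).
    """

    frame: int
    cells: dict[int, CellNode]
    adjacency: nx.Graph
    image: np.ndarray | None = None   # underlying intensity frame, if any


class SpatioTemporalGraph:
    """Linked sequence of frame graphs with event annotations."""

    def __init__(self, frame_graphs: Sequence[FrameGraph],
                 frame_interval: float = 1.0):
        self.frames = list(frame_graphs)
        self.frame_interval = float(frame_interval)
        # (frame, cid) -> list of (frame+1, cid)
        self.successors: dict[tuple[int, int], list[tuple[int, int]]] = {}
        self.predecessors: dict[tuple[int, int], tuple[int, int]] = {}
        self.events: list[Division | Elimination | ErrorCandidate] = []

    # -- structure -----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def cell(self, frame: int, cell_id: int) -> CellNode:
        return self.frames[frame].cells[cell_id]

    def nodes(self) -> Iterator[tuple[int, int]]:
        for fg in self.frames:
            for cid in fg.cells:
                yield (fg.frame, cid)

    def edges(self) -> Iterator[tuple[tuple[int, int], tuple[int, int], str]]:
        for fg in self.frames:
            for a, b in fg.adjacency.edges():
                yield (fg.frame, a), (fg.frame, b), "spatial"
        for src, dsts in self.successors.items():
            for dst in dsts:
                yield src, dst, "temporal"

    def degree_spatial(self, frame: int, cell_id: int) -> int:
        g = self.frames[frame].adjacency
        return g.degree(cell_id) if cell_id in g else 0

    def neighbors_spatial(self, frame: int, cell_id: int) -> list[int]:
        g = self.frames[frame].adjacency
        return list(g.neighbors(cell_id)) if cell_id in g else []

    def _link(self, src: tuple[int, int], dst: tuple[int, int]) -> None:
        self.successors.setdefault(src, []).append(dst)
        self.predecessors[dst] = src

    # -- tracks --------------------------------------------------------
    def track_root(self, frame: int, cell_id: int) -> tuple[int, int]:
        """Follow single-predecessor links back to the cell's first
        appearance (division boundaries start a new track)."""
        node = (frame, cell_id)
        while node in self.predecessors:
            pred = self.predecessors[node]
            if len(self.successors.get(pred, [])) != 1:
                break  # born by division
            node = pred
        return node

    def track_of(self, frame: int, cell_id: int) -> list[tuple[int, int]]:
        """The full chain of (frame, cell_id) for this cell's identity."""
        node = self.track_root(frame, cell_id)
        chain = [node]
        while True:
            succ = self.successors.get(chain[-1], [])
            if len(succ) != 1:
                break
            chain.append(succ[0])
        return chain


# ---------------------------------------------------------------------
# seed tracking and editing
# ---------------------------------------------------------------------

def track_seeds(seed_sets: Sequence[SeedSet],
                max_displacement: float) -> list[SeedTrack]:
    """Greedy nearest-neighbor seed tracking across frames.

    Seeds are matched frame-to-frame in ascending distance order under
    ``max_displacement``.  A track that does not span the whole sequence
    is reported ``broken`` with the frame at which it breaks, surfacing
    likely seeding errors for correction.
    """
    if len(seed_sets) < 2:
        raise ValueError("track_seeds needs at least 2 frames")
    n_frames = len(seed_sets)
    # chains keyed by (frame, seed_id) of their current tail
    open_chains: dict[int, list[tuple[int, int]]] = {}
    tails: dict[int, int] = {}  # seed_id in current frame -> chain index
    chains: list[list[tuple[int, int]]] = []
    for sid, _, _ in seed_sets[0].seeds:
        tails[sid] = len(chains)
        chains.append([(0, sid)])
    starts_late: list[int] = []
    for t in range(1, n_frames):
        prev = {sid: (y, x) for sid, y, x in seed_sets[t - 1].seeds
                if sid in tails}
        cur = {sid: (y, x) for sid, y, x in seed_sets[t].seeds}
        pairs = []
        for pa, (ya, xa) in prev.items():
            for pb, (yb, xb) in cur.items():
                d = float(np.hypot(ya - yb, xa - xb))
                if d <= max_displacement:
                    pairs.append((d, pa, pb))
        pairs.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        new_tails: dict[int, int] = {}
        for d, pa, pb in pairs:
            if pa in used_a or pb in used_b:
                continue
            used_a.add(pa)
            used_b.add(pb)
            ci = tails[pa]
            chains[ci].append((t, pb))
            new_tails[pb] = ci
        for pb in cur:
            if pb not in used_b:
                new_tails[pb] = len(chains)
                chains.append([(t, pb)])
        tails = new_tails
    tracks = []
    for i, members in enumerate(chains):
        first, last = members[0][0], members[-1][0]
        broken = not (first == 0 and last == n_frames - 1)
        tracks.append(SeedTrack(
            track_id=i, members=members,
            status="broken" if broken else "continuous",
            break_frame=(last + 1 if last < n_frames - 1 else
                         (first if first > 0 else None)) if broken else None,
        ))
    return tracks


def apply_seed_edits(s: SeedSet, edits: Sequence[tuple]) -> SeedSet:
    """Apply programmatic seed corrections in order.

    Edits: ``("add", y, x)``, ``("remove", seed_id)``,
    ``("fuse", id_a, id_b)`` (keeps the lower id, at the midpoint).
    Unknown ids raise with the index of the failing edit.
    """
    seeds = {sid: (y, x) for sid, y, x in s.seeds}
    next_id = max(seeds, default=0) + 1
    for i, edit in enumerate(edits):
        op = edit[0]
        if op == "add":
            _, y, x = edit
            seeds[next_id] = (float(y), float(x))
            next_id += 1
        elif op == "remove":
            _, sid = edit
            if sid not in seeds:
                raise ValueError(f"edit {i}: unknown seed id {sid}")
            del seeds[sid]
        elif op == "fuse":
            _, a, b = edit
            if a not in seeds or b not in seeds:
                raise ValueError(f"edit {i}: unknown seed id in fuse({a},{b})")
            ya, xa = seeds[a]
            yb, xb = seeds[b]
            keep, drop = min(a, b), max(a, b)
            del seeds[drop]
            seeds[keep] = ((ya + yb) / 2, (xa + xb) / 2)
        else:
            raise ValueError(f"edit {i}: unknown edit op {op!r}")
    return SeedSet(
        seeds=[(sid, y, x) for sid, (y, x) in sorted(seeds.items())],
        frame_index=s.frame_index,
    )


# ---------------------------------------------------------------------
# geometry extraction
# ---------------------------------------------------------------------

def _prune_spurs(img: np.ndarray) -> tuple[np.ndarray, int]:
    """Iteratively remove skeleton endpoints (dangling edges)."""
    img = img.copy()
    kernel = np.ones((3, 3))
    interior = np.zeros_like(img)
    interior[1:-1, 1:-1] = True   # walls ending at the image edge are real
    total = 0
    while True:
        nb = ndi.convolve(img.astype(np.uint8), kernel, mode="constant") - img
        endpoints = img & (nb <= 1) & interior
        n = int(endpoints.sum())
        if n == 0:
            return img, total
        img &= ~endpoints
        total += n


def _face_polygon(mask: np.ndarray, offset: tuple[int, int]) -> Polygon:
    """Outline of a face mask, traced midway through the boundary line."""
    from skimage import measure

    padded = np.pad(mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    longest = max(contours, key=len)
    # contour coords are (row, col) in padded frame; shift back, to (x, y)
    ys = longest[:, 0] - 1 + offset[0]
    xs = longest[:, 1] - 1 + offset[1]
    poly = Polygon(np.column_stack([xs, ys]))
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda p: p.area)
    return poly


def extract_cells(s: Skeleton, frame_index: int | None = None) -> list[CellNode]:
    """Extract cell faces from a boundary skeleton.

    Dangling spurs are pruned (and logged).  Faces are 4-connected
    background components; the exterior face — a component touching all
    four image edges — is discarded.  Faces touching any image edge are
    flagged ``on_border``.  Pixel-level wall adjacency is attached to each
    cell for downstream graph construction and junction measurements.
    """
    if frame_index is None:
        frame_index = s.frame_index
    img, pruned = _prune_spurs(s.image)
    if pruned:
        logger.info("extract_cells: pruned %d dangling spur pixels", pruned)
    faces, n_faces = ndi.label(~img, structure=_CROSS)
    h, w = img.shape
    border_labels = set(np.unique(np.concatenate([
        faces[0, :], faces[-1, :], faces[:, 0], faces[:, -1]]))) - {0}
    exterior: set[int] = set()
    for lab in border_labels:
        mask = faces == lab
        touches = (int(mask[0, :].any()) + int(mask[-1, :].any())
                   + int(mask[:, 0].any()) + int(mask[:, -1].any()))
        if touches == 4:
            exterior.add(lab)
    # wall adjacency: for each skeleton pixel, face labels in its 8-nbhd
    walls: dict[frozenset, list[tuple[int, int]]] = {}
    fy, fx = np.nonzero(img)
    for y, x in zip(fy.tolist(), fx.tolist()):
        labs = set()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and faces[yy, xx] > 0:
                    labs.add(int(faces[yy, xx]))
        labs -= exterior
        for a in labs:
            for b in labs:
                if a < b:
                    walls.setdefault(frozenset((a, b)), []).append((y, x))
    cells: list[CellNode] = []
    objects = ndi.find_objects(faces)
    for lab in range(1, n_faces + 1):
        if lab in exterior:
            continue
        sl = objects[lab - 1]
        if sl is None:
            continue
        mask = faces[sl] == lab
        poly = _face_polygon(mask, (sl[0].start, sl[1].start))
        cy, cx = poly.centroid.y, poly.centroid.x
        cell_walls = {}
        for key, px in walls.items():
            if lab in key:
                other = next(iter(key - {lab}))
                if len(px) >= 2:  # point contact is not adjacency
                    cell_walls[other] = (float(len(px)), np.array(px))
        cells.append(CellNode(
            frame=frame_index, cell_id=lab, polygon=poly,
            centroid=(cy, cx), area=float(poly.area),
            on_border=lab in border_labels, walls=cell_walls,
        ))
    return cells


def cells_from_polygons(polygons: dict[int, Polygon], frame_index: int,
                        box: tuple[float, float] | None = None,
                        border_tol: float = 1e-6) -> list[CellNode]:
    """Wrap ground-truth tessellation polygons as CellNodes.

    ``box`` = (width, height); cells touching the box boundary are
    flagged ``on_border``.
    """
    cells = []
    for cid, poly in polygons.items():
        on_border = False
        if box is not None:
            minx, miny, maxx, maxy = poly.bounds
            on_border = (minx <= border_tol or miny <= border_tol
                         or maxx >= box[0] - border_tol
                         or maxy >= box[1] - border_tol)
        cells.append(CellNode(
            frame=frame_index, cell_id=cid, polygon=poly,
            centroid=(poly.centroid.y, poly.centroid.x),
            area=float(poly.area), on_border=on_border,
        ))
    return cells


def build_frame_graph(cells: Sequence[CellNode],
                      min_shared: float = 1.0,
                      image: np.ndarray | None = None) -> FrameGraph:
    """Spatial adjacency graph of one frame.

    Adjacency requires a shared boundary of length >= ``min_shared`` px;
    a point contact at a vertex never counts.  Pixel-extracted cells use
    their wall pixels; polygon-only cells use exact boundary
    intersection, with a buffer-based estimate as numerical fallback.
    """
    if not cells:
        return FrameGraph(frame=0, cells={}, adjacency=nx.Graph(), image=image)
    frame = cells[0].frame
    g = nx.Graph()
    cdict = {c.cell_id: c for c in cells}
    g.add_nodes_from(cdict)
    if all(c.walls is not None for c in cells):
        for c in cells:
            for other, (length, px) in c.walls.items():
                if other in cdict and length >= max(min_shared, 2):
                    g.add_edge(c.cell_id, other, length=length, pixels=px)
        return FrameGraph(frame=frame, cells=cdict, adjacency=g, image=image)
    ids = list(cdict)
    polys = [cdict[i].polygon for i in ids]
    tree = shapely.STRtree(polys)
    tol = 0.05
    for i, poly in enumerate(polys):
        for j in tree.query(poly):
            j = int(j)
            if j <= i:
                continue
            inter = poly.exterior.intersection(polys[j].exterior)
            length = inter.length
            if length == 0.0:
                # numerical fallback for not-quite-identical shared edges
                blob = poly.buffer(tol).intersection(polys[j].buffer(tol))
                length = max(0.0, blob.area / (2 * tol) - tol)
                inter = blob
            if length >= min_shared:
                g.add_edge(ids[i], ids[j], length=float(length), geometry=inter)
    return FrameGraph(frame=frame, cells=cdict, adjacency=g, image=image)


# ---------------------------------------------------------------------
# temporal linking
# ---------------------------------------------------------------------

def _match_frames(fg_a: FrameGraph, fg_b: FrameGraph,
                  d_scale: float, min_score: float):
    """Greedy descending-score matching between two frames.

    score = overlap / max(area) - centroid_distance / d_scale.
    Returns (matches a->b, unmatched_a, unmatched_b).
    """
    ids_b = list(fg_b.cells)
    polys_b = [fg_b.cells[i].polygon for i in ids_b]
    tree = shapely.STRtree(polys_b)
    cands = []
    for ca in fg_a.cells.values():
        for jj in tree.query(ca.polygon):
            cb = fg_b.cells[ids_b[int(jj)]]
            overlap = ca.polygon.intersection(cb.polygon).area
            if overlap <= 0:
                continue
            dist = float(np.hypot(ca.centroid[0] - cb.centroid[0],
                                  ca.centroid[1] - cb.centroid[1]))
            score = overlap / max(ca.area, cb.area) - dist / d_scale
            cands.append((score, ca.cell_id, cb.cell_id))
    cands.sort(reverse=True)
    matches: dict[int, int] = {}
    used_b: set[int] = set()
    for score, a, b in cands:
        if score < min_score:
            break
        if a in matches or b in used_b:
            continue
        matches[a] = b
        used_b.add(b)
    unmatched_a = [a for a in fg_a.cells if a not in matches]
    unmatched_b = [b for b in fg_b.cells if b not in used_b]
    return matches, unmatched_a, unmatched_b


def link_frames(frame_graphs: Sequence[FrameGraph],
                d_scale: float = 50.0,
                min_score: float = 0.45,
                division_overlap: float = 0.5,
                elimination_coverage: float = 0.6,
                frame_interval: float = 1.0) -> SpatioTemporalGraph:
    """Link per-frame spatial graphs into a spatiotemporal graph.

    Cells are matched by a greedy descending combination of area overlap
    and centroid distance.  Unmatched cells are then explained:

    * two new cells each overlapping a vanished cell by >=
      ``division_overlap`` of their own area -> :class:`Division`;
    * a vanished interior cell whose footprint is covered by its former
      neighbors in the next frame -> :class:`Elimination`;
    * border cells may enter/leave the field of view silently;
    * anything else -> :class:`ErrorCandidate` (reported, never
      auto-resolved).
    """
    if len(frame_graphs) < 2:
        raise ValueError("link_frames needs at least 2 frames")
    g = SpatioTemporalGraph(frame_graphs, frame_interval=frame_interval)
    for t in range(len(frame_graphs) - 1):
        fa, fb = frame_graphs[t], frame_graphs[t + 1]
        matches, un_a, un_b = _match_frames(fa, fb, d_scale, min_score)
        for a, b in matches.items():
            g._link((t, a), (t + 1, b))
        new_cells = set(un_b)
        vanished = list(un_a)
        # divisions: pairs of new cells covering a vanished mother
        claimed_new: set[int] = set()
        still_vanished = []
        for m in vanished:
            mother = fa.cells[m]
            daughters = []
            for b in new_cells - claimed_new:
                cb = fb.cells[b]
                ov = mother.polygon.intersection(cb.polygon).area
                if ov >= division_overlap * cb.area:
                    daughters.append((ov, b))
            if len(daughters) >= 2:
                daughters.sort(reverse=True)
                d1, d2 = daughters[0][1], daughters[1][1]
                claimed_new.update((d1, d2))
                g._link((t, m), (t + 1, d1))
                g._link((t, m), (t + 1, d2))
                g.events.append(Division(
                    frame=t + 1, mother=(t, m),
                    daughters=((t + 1, d1), (t + 1, d2))))
            else:
                still_vanished.append(m)
        for m in still_vanished:
            mother = fa.cells[m]
            if mother.on_border:
                continue  # lost at the field border
            nb_next = []
            for nb in fa.adjacency.neighbors(m):
                if nb in matches:
                    nb_next.append(fb.cells[matches[nb]].polygon)
            if nb_next:
                cover = mother.polygon.intersection(
                    shapely.unary_union(nb_next)).area / mother.area
            else:
                cover = 0.0
            if cover >= elimination_coverage:
                g.events.append(Elimination(frame=t, cell=(t, m)))
            else:
                g.events.append(ErrorCandidate(
                    frame=t, cell=(t, m),
                    reason="vanished without division/elimination signature"))
        for b in new_cells - claimed_new:
            if not fb.cells[b].on_border:
                g.events.append(ErrorCandidate(
                    frame=t + 1, cell=(t + 1, b),
                    reason="appeared without mother or border contact"))
    return g


# ---------------------------------------------------------------------
# skeleton editing
# ---------------------------------------------------------------------

def edit_skeleton(s: Skeleton, edits: Sequence[tuple]) -> Skeleton:
    """Apply programmatic boundary corrections.

    Edits: ``("add_edge", [(y, x), ...])`` draws a polyline whose
    endpoints must lie on the existing skeleton (otherwise the edit would
    leave an unclosed dangling edge and is rejected);
    ``("remove_edge", (y, x))`` removes the whole wall containing the
    given boundary pixel (merging the two flanking faces).
    """
    from skimage.draw import line

    img = s.image.copy()
    for i, edit in enumerate(edits):
        op = edit[0]
        if op == "add_edge":
            path = [(int(y), int(x)) for y, x in edit[1]]
            if len(path) < 2:
                raise ValueError(f"edit {i}: path needs >= 2 points")
            for p in (path[0], path[-1]):
                y, x = p
                nb = img[max(0, y - 1):y + 2, max(0, x - 1):x + 2]
                if not nb.any():
                    raise ValueError(
                        f"edit {i}: endpoint {p} not on the skeleton; "
                        "the added wall would break face closure")
            for (y0, x0), (y1, x1) in zip(path[:-1], path[1:]):
                rr, cc = line(y0, x0, y1, x1)
                img[rr, cc] = True
        elif op == "remove_edge":
            y, x = edit[1]
            if not img[y, x]:
                raise ValueError(f"edit {i}: ({y},{x}) is not a boundary pixel")
            faces, _ = ndi.label(~img, structure=_CROSS)
            h, w = img.shape
            labs = set()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and faces[yy, xx] > 0:
                        labs.add(int(faces[yy, xx]))
            if len(labs) != 2:
                raise ValueError(
                    f"edit {i}: pixel ({y},{x}) does not separate exactly "
                    f"two faces (found {len(labs)})")
            a, b = sorted(labs)
            fy, fx = np.nonzero(img)
            for yy, xx in zip(fy.tolist(), fx.tolist()):
                nbl = set()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        y2, x2 = yy + dy, xx + dx
                        if 0 <= y2 < h and 0 <= x2 < w and faces[y2, x2] > 0:
                            nbl.add(int(faces[y2, x2]))
                if nbl == {a, b}:
                    img[yy, xx] = False
        else:
            raise ValueError(f"edit {i}: unknown edit op {op!r}")
    return Skeleton(img.astype(np.uint8), frame_index=s.frame_index)
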