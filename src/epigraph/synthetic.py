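"""Ground-truthed synthetic epithelium time-lapses.

The generator is a *kinematic* relaxed-Voronoi model, not a mechanical
vertex model: each cell is the Voronoi cell of a generator point inside a
rectangular field, points drift smoothly between frames, and scripted
events move or replace points so that the tessellation exhibits the
target topology change.  This is sufficient to produce the observables
the analysis modules measure (polygon classes, areas, orientations,
divisions, eliminations, neighbor exchanges) with exact ground truth; it
does not simulate tissue mechanics.

Event mechanics
---------------
* division: the mother's point is replaced by two points placed
  symmetrically about the scripted junction line, so the daughters'
  shared junction lies along the scripted angle;
* elimination: the victim's Delaunay neighbors step toward it for a few
  frames (the cell shrinks), then the point is removed (face removal);
* T1 / intercalation: the quartet's points are displaced along a
  progress variable ``s``; the adjacency flip point ``s*`` is calibrated
  numerically per event (bisection on the actual tessellation), so the
  fast / slow / transient junction-length templates are well-posed.

A renderer embeds the tessellation as bright membrane ridges on a
dome-shaped surface inside a 3D volume, optionally with a sparser,
dimmer decoy layer at a different depth, an intensity gradient, and
noise — emulating a curved two-layer epithelium as seen in confocal
stacks of membrane-labelled tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from .io import ImageStack, Skeleton

__all__ = [
    "TissueFrame", "GroundTruthTissue", "RenderSpec", "RenderResult",
    "ScriptedDivision", "ScriptedT1", "ScriptedElimination",
    "generate_tissue", "render_stack", "division_microfixture",
    "rate_per_frame", "DEFAULT_T1_RATE_PER_1000_PER_HOUR",
]

#: realistic default intercalation rate (transitions per 1,000 cells per hour)
DEFAULT_T1_RATE_PER_1000_PER_HOUR = 13.0


def rate_per_frame(per_1000_per_hour: float, frame_interval_min: float) -> float:
    """Convert a per-1,000-cells-per-hour event rate to per-cell-per-frame."""
    return per_1000_per_hour / 1000.0 * frame_interval_min / 60.0


# ---------------------------------------------------------------------
# script records
# ---------------------------------------------------------------------

@dataclass
class ScriptedDivision:
    frame: int                 # frame where daughters are first visible
    mother: int
    daughters: tuple[int, int]
    junction_angle_deg: float  # orientation of the new junction


@dataclass
class ScriptedT1:
    frame_start: int
    frame_of_exchange: int     # first frame with the new adjacency
    losers: tuple[int, int]    # pair losing their junction
    winners: tuple[int, int]   # pair gaining one
    template: Literal["fast", "slow", "transient"]


@dataclass
class ScriptedElimination:
    frame: int                 # last frame the cell is visible
    cell: int


@dataclass
class TissueFrame:
    index: int
    points: dict[int, tuple[float, float]]
    polygons: dict[int, Polygon]
    adjacency: dict[frozenset, float]   # cell-id pair -> junction length


@dataclass
class GroundTruthTissue:
    frames: list[TissueFrame]
    divisions: list[ScriptedDivision]
    t1_events: list[ScriptedT1]
    eliminations: list[ScriptedElimination]
    box: tuple[float, float]
    frame_interval: float
    rng_seed: int

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def interior_ids(self, t: int, margin: float = 1e-6) -> list[int]:
        w, h = self.box
        out = []
        for cid, poly in self.frames[t].polygons.items():
            minx, miny, maxx, maxy = poly.bounds
            if (minx > margin and miny > margin
                    and maxx < w - margin and maxy < h - margin):
                out.append(cid)
        return out

    def script_json(self) -> str:
        return json.dumps({
            "box": list(self.box),
            "frame_interval": self.frame_interval,
            "rng_seed": self.rng_seed,
            "divisions": [asdict(d) for d in self.divisions],
            "t1_events": [{**asdict(e), "losers": list(e.losers),
                           "winners": list(e.winners)} for e in self.t1_events],
            "eliminations": [asdict(e) for e in self.eliminations],
        }, indent=1, sort_keys=True)

    @staticmethod
    def script_from_json(text: str) -> dict:
        d = json.loads(text)
        d["divisions"] = [ScriptedDivision(
            frame=x["frame"], mother=x["mother"],
            daughters=tuple(x["daughters"]),
            junction_angle_deg=x["junction_angle_deg"]) for x in d["divisions"]]
        d["t1_events"] = [ScriptedT1(
            frame_start=x["frame_start"], frame_of_exchange=x["frame_of_exchange"],
            losers=tuple(x["losers"]), winners=tuple(x["winners"]),
            template=x["template"]) for x in d["t1_events"]]
        d["eliminations"] = [ScriptedElimination(
            frame=x["frame"], cell=x["cell"]) for x in d["eliminations"]]
        return d


# ---------------------------------------------------------------------
# Voronoi tessellation in a box (reflection construction: exact clipping)
# ---------------------------------------------------------------------

def _voronoi_frame(points: dict[int, np.ndarray],
                   box: tuple[float, float], index: int) -> TissueFrame:
    ids = sorted(points)
    P = np.array([points[i] for i in ids], dtype=np.float64)
    w, h = box
    mirrors = [P * [1, -1], P * [1, -1] + [0, 2 * h],
               P * [-1, 1], P * [-1, 1] + [2 * w, 0]]
    allp = np.vstack([P] + mirrors)
    vor = Voronoi(allp)
    n = len(ids)
    polys = {}
    for k, cid in enumerate(ids):
        region = vor.regions[vor.point_region[k]]
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid:
            poly = poly.buffer(0)
        polys[cid] = poly
    adjacency: dict[frozenset, float] = {}
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p < n and q < n and min(verts) >= 0:
            a, b = vor.vertices[verts[0]], vor.vertices[verts[1]]
            adjacency[frozenset((ids[p], ids[q]))] = float(np.hypot(*(a - b)))
    return TissueFrame(index=index,
                       points={i: tuple(points[i]) for i in ids},
                       polygons=polys, adjacency=adjacency)


def _lloyd_relax(P: np.ndarray, box: tuple[float, float],
                 iters: int) -> np.ndarray:
    pts = {i: P[i] for i in range(len(P))}
    for _ in range(iters):
        fr = _voronoi_frame(pts, box, 0)
        pts = {i: np.array([fr.polygons[i].centroid.x,
                            fr.polygons[i].centroid.y]) for i in pts}
    return np.array([pts[i] for i in range(len(P))])


# ---------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------

class _GenerationError(ValueError):
    pass


def _junction_signed(points: dict[int, np.ndarray], box, losers, winners,
                     ) -> float:
    """+length of the losers' junction, -length of the winners', 0 at
    the fourfold vertex.  Depends only on the tessellation."""
    fr = _voronoi_frame(points, box, 0)
    l_key = frozenset(losers)
    w_key = frozenset(winners)
    if l_key in fr.adjacency:
        return fr.adjacency[l_key]
    if w_key in fr.adjacency:
        return -fr.adjacency[w_key]
    return 0.0


class _ActiveT1:
    """A scripted neighbor exchange being played out."""

    def __init__(self, quartet, base, box, template, frame_start, points):
        self.losers = quartet[:2]
        self.winners = quartet[2:]
        self.base = dict(base)          # id -> base position
        self.box = box
        self.template = template
        self.frame_start = frame_start
        A, B = (self.base[i] for i in self.losers)
        C, D = (self.base[i] for i in self.winners)
        self.mid = (A + B) / 2
        self.u = (B - A) / np.linalg.norm(B - A)
        self.dab = float(np.linalg.norm(B - A))
        self._points_ref = points
        self.schedule: list[float] = []
        self.frame_of_exchange: int | None = None

    def positions(self, s: float) -> dict[int, np.ndarray]:
        A, B = (self.base[i] for i in self.losers)
        C, D = (self.base[i] for i in self.winners)
        beta, alpha = 0.35, 0.8
        return {
            self.losers[0]: A - s * beta * self.dab / 2 * self.u,
            self.losers[1]: B + s * beta * self.dab / 2 * self.u,
            self.winners[0]: C + s * alpha * (self.mid - C),
            self.winners[1]: D + s * alpha * (self.mid - D),
        }

    def _adjacency_at(self, s: float) -> dict:
        key = round(s, 9)
        cached = self._adj_cache.get(key)
        if cached is None:
            pts = dict(self._points_ref)
            pts.update(self.positions(s))
            cached = _voronoi_frame(pts, self.box, 0).adjacency
            self._adj_cache[key] = cached
        return cached

    def _length(self, s: float) -> float:
        adj = self._adjacency_at(s)
        l_key = frozenset(self.losers)
        w_key = frozenset(self.winners)
        if l_key in adj:
            return adj[l_key]
        if w_key in adj:
            return -adj[w_key]
        return 0.0

    def _side_edges(self, s: float):
        quartet = set(self.losers) | set(self.winners)
        exchange = {frozenset(self.losers), frozenset(self.winners)}
        return {key: length
                for key, length in self._adjacency_at(s).items()
                if key & quartet and key not in exchange}

    def _side_ok(self, s: float, min_len: float = 1.3) -> bool:
        """The *other* junctions of the quartet must not graze zero: the
        scripted exchange has to be the only topology change."""
        return all(length >= min_len
                   for length in self._side_edges(s).values())

    def calibrate(self) -> bool:
        """Find the flip point and build the template schedule; returns
        False if this quartet cannot flip cleanly within the stroke."""
        self._adj_cache: dict = {}
        # cheap screens first: stroke must flip, and side junctions must
        # stay clear at both ends of the stroke
        if self._length(0.0) < 3.2 or not self._side_ok(0.0):
            return False
        if self._length(1.0) > -4.5 or not self._side_ok(1.0):
            return False
        lo, hi = 0.0, 1.0
        for _ in range(16):  # s*: adjacency flip point
            mid = (lo + hi) / 2
            if self._length(mid) > 0:
                lo = mid
            else:
                hi = mid
        s_star_lo, s_star_hi = lo, hi

        def s_at(target: float) -> float:
            # s with junction length ~ target (signed); length decreases in s
            a, b = (0.0, s_star_lo) if target > 0 else (s_star_hi, 1.0)
            for _ in range(14):
                mid = (a + b) / 2
                if self._length(mid) > target:
                    a = mid
                else:
                    b = mid
            return (a + b) / 2

        sa = s_at(2.5)
        sb = s_at(-2.5)
        hold = s_at(-4.0)
        # the leading half-step keeps per-frame displacements trackable
        if self.template == "fast":
            self.schedule = [0.0, sa / 2, sa, sb, hold]
            self.frame_of_exchange = self.frame_start + 3
        elif self.template == "slow":
            self.schedule = [0.0, sa / 2, sa, s_at(0.8), s_at(0.45),
                             s_at(0.15), sb, hold]
            self.frame_of_exchange = self.frame_start + 6
        elif self.template == "transient":
            self.schedule = [0.0, sa / 2, sa, sb, sa, sb, hold]
            self.frame_of_exchange = self.frame_start + 3
        else:
            raise _GenerationError(f"unknown T1 template {self.template!r}")
        # side junctions must stay clear of zero AND keep the identical
        # topology at every anchor: the exchange is the only change
        side_sets = [frozenset(self._side_edges(s)) for s in self.schedule]
        ok = (all(self._side_ok(s) for s in self.schedule)
              and all(ss == side_sets[0] for ss in side_sets))
        self._adj_cache.clear()
        return ok


def generate_tissue(n_cells: int,
                    n_frames: int,
                    event_rates: dict[str, float] | None = None,
                    rng_seed: int = 0,
                    *,
                    box: tuple[float, float] | None = None,
                    mean_cell_area: float = 900.0,
                    jitter: float = 0.15,
                    relax_iters: int = 6,
                    frame_interval: float = 6.0,
                    divisions: Sequence[dict] | None = None,
                    t1s: Sequence[dict] | None = None,
                    eliminations: Sequence[dict] | None = None,
                    ) -> GroundTruthTissue:
    """Generate a ground-truthed synthetic epithelium sequence.

    Parameters
    ----------
    n_cells : int
        Initial cell count (>= 4).
    n_frames : int
        Number of frames.
    event_rates : dict, optional
        Per-cell per-frame probabilities, keys among
        ``{"division", "t1", "elimination"}`` (see :func:`rate_per_frame`
        to convert the field's per-1,000-cells-per-hour convention).
    rng_seed : int
        Everything (layout, jitter, event placement) derives from this.
    box : (width, height), optional
        Field size in px; default sized for ``mean_cell_area`` (the
        packing regime of a dense columnar epithelium, ~30 px across).
    jitter : float
        Smooth per-frame point drift (px/frame).
    frame_interval : float
        Minutes between frames.
    divisions, t1s, eliminations : sequences of dict, optional
        Explicit scripts, e.g. ``{"frame": 5, "mother": 3, "angle": 45}``,
        ``{"frame": 2, "template": "slow"}``, ``{"frame": 4, "cell": 7}``.
        Unspecified choices are drawn from the rng.

    Raises
    ------
    ValueError
        For infeasible scripts (e.g. no eligible quartet for a T1).
    """
    if n_cells < 4:
        raise ValueError("n_cells must be >= 4")
    rng = np.random.default_rng(rng_seed)
    if box is None:
        side = float(np.sqrt(n_cells * mean_cell_area))
        box = (side, side)
    w, h = box
    P = rng.uniform([0, 0], [w, h], size=(n_cells, 2))
    P = _lloyd_relax(P, box, relax_iters)
    points: dict[int, np.ndarray] = {i: P[i] for i in range(n_cells)}
    velocity: dict[int, np.ndarray] = {i: np.zeros(2) for i in points}
    next_id = n_cells

    rates = dict(event_rates or {})
    div_script = {d["frame"]: d for d in (divisions or [])}
    t1_script: dict[int, list[dict]] = {}
    for e in (t1s or []):
        t1_script.setdefault(e["frame"], []).append(e)
    elim_script = {e["frame"]: e for e in (eliminations or [])}

    frames: list[TissueFrame] = []
    rec_div: list[ScriptedDivision] = []
    rec_t1: list[ScriptedT1] = []
    rec_elim: list[ScriptedElimination] = []
    active_t1: list[_ActiveT1] = []
    shrinking: dict[int, int] = {}         # victim -> frames left
    busy: set[int] = set()

    cur = _voronoi_frame(points, box, 0)
    frames.append(cur)

    def interior_free(fr: TissueFrame) -> list[int]:
        w_, h_ = box
        out = []
        for cid, poly in fr.polygons.items():
            if cid in busy:
                continue
            minx, miny, maxx, maxy = poly.bounds
            if minx > 1 and miny > 1 and maxx < w_ - 1 and maxy < h_ - 1:
                out.append(cid)
        return out

    def start_t1(t: int, template: str | None) -> bool:
        if template is None:
            template = str(rng.choice(["fast", "slow", "transient"]))
        ok_ids = set(interior_free(cur))
        edges = [tuple(sorted(k)) for k, L in cur.adjacency.items()
                 if 3.5 <= L <= 9.0 and set(k) <= ok_ids]
        rng.shuffle(edges)
        adj = {k for k in cur.adjacency}
        nbrs: dict[int, set[int]] = {}
        for k in cur.adjacency:
            a, b = tuple(k)
            nbrs.setdefault(a, set()).add(b)
            nbrs.setdefault(b, set()).add(a)
        for a, b in edges:
            common = [c for c in nbrs[a] & nbrs[b] if c in ok_ids]
            if len(common) != 2:
                continue
            c, d = common
            if frozenset((c, d)) in adj:
                continue
            ev = _ActiveT1((a, b, c, d),
                           {i: points[i].copy() for i in (a, b, c, d)},
                           box, template, t, points)
            if ev.calibrate():
                ring = {a, b, c, d}
                for q in (a, b, c, d):
                    ring |= nbrs.get(q, set())
                ev.frozen = ring
                active_t1.append(ev)
                busy.update(ring)
                rec_t1.append(ScriptedT1(
                    frame_start=t, frame_of_exchange=ev.frame_of_exchange,
                    losers=(a, b), winners=(c, d), template=template))
                return True
        return False

    for t in range(1, n_frames):
        # 1. smooth drift for unconstrained points
        for i in points:
            if i in busy or i in shrinking:
                continue
            velocity[i] = 0.8 * velocity[i] + 0.6 * jitter * rng.standard_normal(2)
            points[i] = np.clip(points[i] + velocity[i], [2, 2], [w - 2, h - 2])
        # 2. ongoing eliminations: neighbors close in on the victim
        for victim in list(shrinking):
            nb = [next(iter(k - {victim})) for k in cur.adjacency if victim in k]
            for q in nb:
                if q in points:
                    points[q] = points[q] + 0.12 * (points[victim] - points[q])
            shrinking[victim] -= 1
            if shrinking[victim] <= 0:
                del points[victim], velocity[victim]
                del shrinking[victim]
                busy.discard(victim)
        # 3. ongoing T1s
        for ev in list(active_t1):
            step = t - ev.frame_start
            if step < len(ev.schedule):
                s = ev.schedule[step]
            else:
                s = ev.schedule[-1]
            pos = ev.positions(s)
            for i, p in pos.items():
                points[i] = p
            if step >= len(ev.schedule):
                quartet = set(ev.losers) | set(ev.winners)
                for q in ev.frozen:
                    if q in quartet:
                        continue  # the exchanged quartet stays pinned
                    busy.discard(q)
                    if q in velocity:
                        velocity[q] = np.zeros(2)  # resume drift gently
                active_t1.remove(ev)
        # 4. scheduled / drawn events starting this frame
        n_live = len(points)
        want_div = 1 if t in div_script else rng.binomial(
            n_live, min(1.0, rates.get("division", 0.0)))
        want_t1 = len(t1_script.get(t, [])) or rng.binomial(
            n_live, min(1.0, rates.get("t1", 0.0)))
        want_elim = 1 if t in elim_script else rng.binomial(
            n_live, min(1.0, rates.get("elimination", 0.0)))
        for k in range(want_t1):
            entries = t1_script.get(t, [])
            entry = entries[k] if k < len(entries) else None
            template = entry.get("template") if entry else None
            if not start_t1(t, template) and entry is not None:
                # no clean quartet right now: defer the scripted event
                # (the recorded script reflects realized frames)
                if t + 1 >= n_frames - 8:
                    raise ValueError(
                        f"no eligible quartet for scripted T1 at frame {t}")
                t1_script.setdefault(t + 1, []).append(entry)
            # positions for frame t are the event's s(0) = baseline
        for _ in range(want_elim):
            script = elim_script.get(t, {})
            victim = script.get("cell")
            cands = interior_free(cur)
            if victim is None:
                if not cands:
                    continue
                victim = int(rng.choice(cands))
            elif victim not in points:
                raise ValueError(f"scripted elimination: no cell {victim}")
            shrink_frames = 4
            shrinking[victim] = shrink_frames
            busy.add(victim)
            # pin the closing ring so the scripted elimination does not
            # trigger secondary neighbor exchanges around it
            busy.update(next(iter(k - {victim}))
                        for k in cur.adjacency if victim in k)
            rec_elim.append(ScriptedElimination(
                frame=t + shrink_frames - 1, cell=victim))
        for _ in range(want_div):
            script = div_script.get(t, {})
            mother = script.get("mother")
            cands = interior_free(cur)
            if mother is None:
                if not cands:
                    continue
                mother = int(rng.choice(cands))
            elif mother not in points:
                raise ValueError(f"scripted division: no cell {mother}")
            angle = script.get("angle")
            if angle is None:
                angle = float(rng.uniform(0, 180))
            area = cur.polygons[mother].area
            r_eq = float(np.sqrt(area / np.pi))
            sep = np.deg2rad(angle + 90.0)
            u = np.array([np.cos(sep), np.sin(sep)])
            base = points.pop(mother)
            velocity.pop(mother, None)
            d1, d2 = next_id, next_id + 1
            next_id += 2
            off = 0.55 * r_eq * u
            points[d1] = np.clip(base + off, [2, 2], [w - 2, h - 2])
            points[d2] = np.clip(base - off, [2, 2], [w - 2, h - 2])
            velocity[d1] = np.zeros(2)
            velocity[d2] = np.zeros(2)
            # pin the daughters and the mother's former ring: the new
            # junction settles without bystander exchanges
            busy.update({d1, d2})
            busy.update(next(iter(k - {mother}))
                        for k in cur.adjacency if mother in k)
            rec_div.append(ScriptedDivision(
                frame=t, mother=mother, daughters=(d1, d2),
                junction_angle_deg=angle % 180.0))
        cur = _voronoi_frame(points, box, t)
        frames.append(cur)

    return GroundTruthTissue(
        frames=frames, divisions=rec_div, t1_events=rec_t1,
        eliminations=rec_elim, box=box, frame_interval=frame_interval,
        rng_seed=rng_seed)


# ---------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------

@dataclass
class RenderSpec:
    """How to embed a tissue into a 3D image volume.

    The target layer sits on a Gaussian dome
    ``z = z_base + dome_amplitude * exp(-rho^2 / (2 dome_sigma^2))``; the
    decoy layer (a coarser, dimmer tessellation emulating a squamous
    second cell layer) sits ``decoy_offset`` slices above it.
    """

    n_z: int = 1
    z_base: float = 0.0
    dome_amplitude: float = 0.0      # slices
    dome_sigma: float | None = None  # px; default 0.5 * min(box)
    decoy_offset: float = 0.0        # slices; 0 disables the decoy layer
    decoy_cell_scale: float = 3.0    # decoy cells are this much larger (linear)
    decoy_intensity: float = 0.6     # fraction of membrane_intensity
    membrane_width: float = 2.0      # px
    membrane_intensity: float = 200.0
    interior_intensity: float = 30.0
    background: float = 10.0
    noise_sigma: float = 6.0
    poisson: bool = False
    gradient_amplitude: float = 0.0  # 0..1 multiplicative falloff across x
    frame_interval: float = 6.0


@dataclass
class RenderResult:
    stack: ImageStack
    surfaces: list[np.ndarray]           # ground-truth z(y, x) per frame
    skeletons: list[Skeleton]            # ground-truth boundary skeletons
    label_maps: list[np.ndarray]         # ground-truth cell labels
    decoy_skeletons: list[np.ndarray]    # decoy-layer ridge masks


def _rasterize(polygons: dict[int, Polygon], shape: tuple[int, int]
               ) -> np.ndarray:
    from skimage.draw import polygon as draw_polygon
    from scipy import ndimage as ndi

    labels = np.zeros(shape, dtype=np.int32)
    for cid, poly in polygons.items():
        if poly.is_empty:
            continue
        xs, ys = poly.exterior.coords.xy
        rr, cc = draw_polygon(np.asarray(ys), np.asarray(xs), shape=shape)
        labels[rr, cc] = cid + 1  # label = cell id + 1 (0 is reserved)
    if (labels == 0).any():  # fill rasterization cracks with nearest label
        _, (iy, ix) = ndi.distance_transform_edt(labels == 0,
                                                 return_indices=True)
        labels = labels[iy, ix]
    return labels


def _boundary_of(labels: np.ndarray) -> np.ndarray:
    skel = np.zeros(labels.shape, dtype=bool)
    skel[:-1, :] |= labels[:-1, :] != labels[1:, :]
    skel[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    return skel


def _membrane_profile(skel: np.ndarray, width: float) -> np.ndarray:
    from scipy import ndimage as ndi

    d = ndi.distance_transform_edt(~skel)
    return np.exp(-0.5 * (d / (width / 2.0)) ** 2)


def render_stack(t: GroundTruthTissue, spec: RenderSpec,
                 rng_seed: int | None = None) -> RenderResult:
    """Render a tissue as an 8-bit image stack, with full ground truth.

    The returned :class:`RenderResult` carries the stack plus the true
    surface, per-frame boundary skeletons and label maps, and the decoy
    layer's ridge masks (for contamination checks).
    """
    if rng_seed is None:
        rng_seed = t.rng_seed + 1
    rng = np.random.default_rng(rng_seed)
    w, h = t.box
    ny, nx = int(round(h)), int(round(w))
    sigma = spec.dome_sigma if spec.dome_sigma is not None else 0.5 * min(w, h)
    yy, xx = np.mgrid[0:ny, 0:nx]
    rho2 = (xx - nx / 2) ** 2 + (yy - ny / 2) ** 2
    surface = spec.z_base + spec.dome_amplitude * np.exp(-rho2 / (2 * sigma ** 2))
    surface = np.clip(surface, 0, max(spec.n_z - 1, 0))
    gradient = 1.0 - spec.gradient_amplitude * (xx / max(nx - 1, 1))

    decoy_skel = np.zeros((ny, nx), dtype=bool)
    if spec.decoy_offset > 0:
        n_decoy = max(4, int(len(t.frames[0].points)
                             / spec.decoy_cell_scale ** 2))
        drng = np.random.default_rng(rng_seed + 7)
        DP = drng.uniform([0, 0], [w, h], size=(n_decoy, 2))
        DP = _lloyd_relax(DP, t.box, 3)
        dfr = _voronoi_frame({i: DP[i] for i in range(n_decoy)}, t.box, 0)
        decoy_skel = _boundary_of(_rasterize(dfr.polygons, (ny, nx)))

    frames3d: list[np.ndarray] = []
    surfaces, skels, labmaps, decoys = [], [], [], []
    for fr in t.frames:
        labels = _rasterize(fr.polygons, (ny, nx))
        skel = _boundary_of(labels)
        memb = _membrane_profile(skel, spec.membrane_width)
        signal = (spec.interior_intensity
                  + (spec.membrane_intensity - spec.interior_intensity) * memb)
        signal = signal * gradient
        if spec.n_z == 1:
            plane = spec.background + signal
            if spec.decoy_offset > 0:
                pass  # a single-slice volume cannot hold a second layer
            vol = plane[None]
        else:
            vol = np.full((spec.n_z, ny, nx), spec.background, dtype=np.float64)
            z0 = np.floor(surface).astype(int)
            fz = surface - z0
            z1 = np.minimum(z0 + 1, spec.n_z - 1)
            np.add.at(vol, (z0, yy, xx), signal * (1 - fz))
            np.add.at(vol, (z1, yy, xx), signal * fz)
            if spec.decoy_offset > 0:
                dz = np.clip(surface + spec.decoy_offset, 0, spec.n_z - 1)
                dmemb = _membrane_profile(decoy_skel, spec.membrane_width * 1.5)
                dsig = spec.decoy_intensity * spec.membrane_intensity * dmemb
                d0 = np.floor(dz).astype(int)
                fd = dz - d0
                d1 = np.minimum(d0 + 1, spec.n_z - 1)
                np.add.at(vol, (d0, yy, xx), dsig * (1 - fd))
                np.add.at(vol, (d1, yy, xx), dsig * fd)
        if spec.poisson:
            vol = rng.poisson(np.clip(vol, 0, None)).astype(np.float64)
        if spec.noise_sigma > 0:
            vol = vol + rng.normal(0, spec.noise_sigma, vol.shape)
        frames3d.append(np.clip(vol, 0, 255).astype(np.uint8))
        surfaces.append(surface.copy())
        skels.append(Skeleton(skel.astype(np.uint8), frame_index=fr.index))
        labmaps.append(labels)
        decoys.append(decoy_skel.copy())
    stack = ImageStack(frames3d, dtype_bits=8,
                       frame_interval=spec.frame_interval)
    return RenderResult(stack=stack, surfaces=surfaces, skeletons=skels,
                        label_maps=labmaps, decoy_skeletons=decoys)


# ---------------------------------------------------------------------
# analytic division fixture
# ---------------------------------------------------------------------

def division_microfixture(mother_angle_deg: float,
                          junction_angle_deg: float,
                          *,
                          n_pre: int = 13,
                          n_post: int = 5,
                          elong: float = 2.0,
                          size: float = 20.0,
                          jitter_deg: float = 0.0,
                          frame_interval: float = 6.0,
                          rng: np.random.Generator | None = None):
    """A minimal tracked-division sequence with exactly known geometry.

    The mother is an elongated 32-gon (long axis at ``mother_angle_deg``)
    for ``n_pre`` frames; the daughters are two rectangles sharing their
    junction edge along ``junction_angle_deg`` for ``n_post`` frames, so
    the daughter centroid segment is exactly perpendicular to the
    junction.  Per-frame angular jitter emulates measurement noise.

    Returns ``(SpatioTemporalGraph, Division)``.
    """
    from .graph import build_frame_graph, cells_from_polygons, link_frames, Division

    if rng is None:
        rng = np.random.default_rng(0)
    cx = cy = 4 * size

    def rot(deg):
        a = np.deg2rad(deg)
        return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])

    def mother_poly(angle):
        th = np.linspace(0, 2 * np.pi, 33)[:-1]
        pts = np.column_stack([elong * size * np.cos(th), size * np.sin(th)])
        pts = pts @ rot(angle).T + [cx, cy]
        return Polygon(pts)

    def daughter_polys(angle):
        # junction edge along `angle`; daughters stacked perpendicular
        L, W = 1.5 * size, 0.6 * size
        rect = np.array([[-L / 2, 0], [L / 2, 0], [L / 2, W], [-L / 2, W]])
        d1 = rect @ rot(angle).T + [cx, cy]
        d2 = (rect * [1, -1]) @ rot(angle).T + [cx, cy]
        return Polygon(d1), Polygon(d2)

    fgs = []
    for f in range(n_pre):
        a = mother_angle_deg + jitter_deg * rng.standard_normal()
        cells = cells_from_polygons({1: mother_poly(a)}, f)
        fgs.append(build_frame_graph(cells))
    for f in range(n_pre, n_pre + n_post):
        a = junction_angle_deg + jitter_deg * rng.standard_normal()
        p1, p2 = daughter_polys(a)
        cells = cells_from_polygons({2: p1, 3: p2}, f)
        fgs.append(build_frame_graph(cells))
    g = link_frames(fgs, frame_interval=frame_interval)
    divs = [e for e in g.events if isinstance(e, Division)]
    if len(divs) != 1:
        raise RuntimeError(f"microfixture produced {len(divs)} divisions")
    return g, divs[0]
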