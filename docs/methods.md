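# Methods

This note documents the models, algorithms, parameter conventions and
design choices behind `epigraph`, and what the synthetic benchmarks do and
do not establish about real data.

## Coordinate and intensity conventions

Pixels are 0-based, (row = y, col = x); z increases away from the
objective. Shapely polygons are stored in (x, y) axis order; every public
centroid is (y, x). All intensity-valued parameters are interpreted on a
0–255 scale; 16-bit stacks are divided by 257 at load so one parameter
table serves both bit depths. Orientations are undirected axes in
[0°, 180°); orientation differences are folded to [0°, 90°].

## Selective plane projection

The projection assumes the target layer carries most of the
high-intensity signal. Per (x, y) column, the z of maximal intensity
(after 3D Gaussian pre-smoothing with `SmoothingRadius`) gives one
candidate surface point; columns with zero maximum are dropped. A
penalized grid smoother is then fit twice:

* the height field minimizes Σ w (z − obs)² + λ·‖D²z‖², where D² collects
  second differences along grid rows and columns and λ = stiffness².
  Affine (and twisted-plane) surfaces lie in the penalty's null space, so
  planes are reproduced exactly at any stiffness; the penalty term is
  non-increasing in stiffness (the monotone-stiffness contract, asserted
  by a property test). Observations are binned on a coarse grid
  (`grid_step` = 4 px) and the solution is bilinearly upsampled with
  linear extrapolation at the borders.
* pass 1 uses `SurfSmoothness1` (default 30): stiff enough that a sparse
  decoy layer several slices away barely deflects the fit. Points with
  |z − surface| > `ProjectionDepthThreshold` (default 1.2, in z-slices —
  the only scale on which 1.2 separates layers ~5 slices apart) are
  discarded. Pass 2 refits with `SurfSmoothness2` (default 20).

Intensity is sampled as the maximum over z ∈ [z₀ − 0.5, z₀ + 0.5] slices
with linear interpolation at the band ends. The original method states
only that intensities "along the surface" are used; the ±half-slice band
is this package's choice, robust to half-slice surface error, and makes
projection exactly idempotent on flat single-plane stacks.

## Segmentation

**Seed generation.** The frame is smoothed with `sigma1`; an intensity
threshold rises from `threshold` in steps of 1 intensity level (the sweep
step is not specified by the original description; 1 level on the 0–255
scale is the finest deterministic choice). At each level, 4-connected
sub-threshold components containing no existing region and with area ≥
`mincellsize` become new regions; components containing exactly one
region extend it; components spanning several regions leave them intact,
preserving the separating ridge. After the sweep, adjacent regions are
fused when

    (mean ridge intensity − min interior mean) / (global ridge maximum)
        < MergeCriteria,

with ridges obtained from a marker watershed of the smoothed frame. The
original tool names the parameter ("Boundary Low Intensity Ratio") but
not the formula; this realization is unit-tested in isolation. One seed
per final region is placed at the region pixel nearest its centroid.

**Region growing.** A priority-flood watershed on the `sigma3`-smoothed
frame: pixels enter a priority queue keyed by (intensity, insertion
counter) — first-come wins, which makes the label map a deterministic
function of image and seeds. Growth is 4-connected; a pixel reached while
already flanked by a different region becomes boundary (label 0), giving
8-connected boundary lines (the standard digital-topology pairing). An
exhaustive linear-scan implementation of the same rule serves as a
bit-exact oracle in the tests. Post-passes: boundary segments whose mean
raw-frame intensity is below `IBoundMax` fuse their flanking regions in a
single ascending-intensity pass; regions larger than `LargeCellSizeThres`
are relabelled background and logged (the original's semantics —
exclusion vs. flagging — are unstated; exclusion keeps downstream
statistics clean).

**Registration** is integer-pixel translation by phase correlation,
chained frame-to-frame, with shifts capped (default: a quarter of the
image side) so featureless frames cannot drift. Sub-pixel shifts and
rotation are out of scope. CLAHE (`equalize_adapthist`) implements the
contrast-enhancement step; the `#` skip token maps to `None`.

## Cell graph

Faces of the 1-px boundary skeleton become cells (spurs pruned, except at
the image border where walls legitimately terminate; the exterior face —
touching all four image edges — is discarded; faces touching any edge are
flagged `on_border`). Adjacency requires a shared wall of ≥ 1 px (≥ 2
co-adjacent boundary pixels in the pixel route); vertex point-contact
never counts. Cell area is the shoelace area of the face outline traced
midway through the boundary line, so a k×k-pixel face has area ≈ k².

Temporal matching scores candidate pairs by
overlap/max(area) − centroid distance / d_scale (d_scale = 50 px) and
accepts greedily in descending order above a minimum score (0.45). The
minimum matters: a mother-to-daughter pair scores ≈ 0.5 on overlap, so
without the floor a symmetric division would be swallowed as a track
continuation. Two unmatched new cells each overlapping a vanished cell by
≥ 50 % of their own area make a Division; a vanished interior cell whose
footprint is ≥ 60 % covered by its former neighbors' next-frame polygons
is an Elimination; border cells may enter and leave silently; everything
else becomes an ErrorCandidate, which is only ever reported — automated
correction is deliberately not attempted.

## Analyses

* **Polygon class** = spatial degree; border cells are excluded from
  distributions (their neighborhood is censored) but still count as
  neighbors of interior cells.
* **Geometry**: shoelace area; elongation and axis from the closed-form
  second central moments of the polygon (ratio = √(λ₁/λ₂)); 1.3 is the
  conventional cut for "significantly elongated".
* **Division orientation**: the mother's long axis is averaged over five
  time points 72–48 min before the division (at the default 6-min frame
  interval: frames −12 … −8), excluding the 36–6 min pre-mitotic rounding
  window where the axis estimate is unreliable; the statement "five time
  points from 72 to 42 min" spans six grid points at 6-min spacing, so
  this package takes the five points 72, 66, 60, 54, 48 and exposes the
  window as a parameter. The new junction's angle is the perpendicular to
  the daughter centroid segment in each of the first five post-division
  frames. The result is the mean of the 25 folded pre×post differences;
  angles are folded because axis and junction are undirected.
* **T1 detection** anchors on the loss of a junction: when a tracked pair
  loses adjacency, every pair of their common neighbors that was not
  adjacent forms a candidate quartet; the signed series (old junction
  positive, new junction negative, 0 at the fourfold vertex) then decides
  whether the exchange completed. Requiring both configurations to reach
  ≥ 2.5 px discards segmentation flicker; the loss may be separated from
  the gain by a multi-frame fourfold vertex, which is why loss and gain
  are not required to be simultaneous. Repeated flips of one quartet are
  one ongoing event. Divisions cannot masquerade as T1s because a
  daughter's track does not span the exchange.
* **T1 classes**: with ε = 1 px and K = 2 frames — *censored* if the new
  configuration never reaches −ε; *transient* if the old configuration
  returns (> +ε) after first completion; *fast* if at most K frames sit
  within ε of zero around the exchange; otherwise *slow*. The original
  classification rules live in unavailable supplementary material; this
  rule reproduces the verbal definitions (decisive-and-stable vs.
  slow-to-stabilize vs. fluctuating) and all constants are exposed.
* **Rate**: count / (mean interior cells / 1000) / hours.

## Synthetic ground truth

The generator is a *kinematic* relaxed-Voronoi model — cells are Voronoi
cells of points in a box (exact clipping via mirror points), initialized
by Lloyd relaxation (6 iterations ≈ the near-hexagonal packing regime of
a columnar epithelium; mean polygon class 6.0 ± 0.1 at 1,000 cells),
drifting by a smooth autoregressive jitter (default 0.15 px/frame;
"clean" event fixtures use 0.05, at which no spontaneous neighbor
exchanges occur over tens of frames). It is not a mechanical vertex
model: forces, tensions and pressures are absent, so it validates
*measurement* machinery, not tissue mechanics.

Scripted events move generator points: divisions replace the mother's
point by two points placed symmetrically about the scripted junction
line; eliminations pull the victim's neighbors inward for four frames
(the cell shrinks) before the point is removed; T1s displace the quartet
along a progress variable whose adjacency flip point is calibrated by
bisection on the actual tessellation, so the fast / slow / transient
length templates hit their near-zero dwell frames exactly. Because the
junction between two Voronoi cells depends only on the four points of its
quartet, freezing the quartet and its first ring during (and the quartet
after) an event pins the scripted series against drift; candidate
quartets whose *side* junctions would graze zero during the stroke are
rejected, so the scripted exchange is the only topology change — this is
what makes precision/recall and the winners-gain/losers-lose ±1 checks
well-posed. The default intercalation rate offered by the generator is
13 per 1,000 cells per hour, a realistic figure for a proliferating disc
epithelium.

Rendering rasterizes the tessellation, draws membranes as Gaussian-profile
ridges (width 2 px) on a Gaussian dome, adds a coarser, dimmer decoy
tessellation at a fixed slice offset, a multiplicative intensity gradient,
and Gaussian (optionally Poisson) noise, returning the stack together
with the true surface, skeletons and label maps. The renderer does not
simulate a PSF, depth attenuation, or photobleaching; segmentation scores
on these fixtures are therefore upper bounds for real movies.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen as
the smallest sizes at which the statistical checks are meaningful: a
20-cell dome stack (≈134² × 24 voxels) for projection; ~200 cells on a
~424² frame for segmentation; 200–250-cell tissues over 20–40 frames for
tracking, events and rates; 1,000 cells for packing statistics; 200
analytic micro-fixtures for orientation statistics.

## Known limitations

* 2D analysis on a projected surface; no volumetric segmentation, and no
  curvature correction of areas/lengths measured on the projection.
* The matching, division, elimination and T1-classification thresholds
  are this package's own (documented above); the original tool names the
  steps but not the constants.
* Greedy mutual-best matching can mislabel events under very large
  inter-frame motion (> ~half a cell diameter per frame).
* The elimination script necessarily rearranges the closing ring
  (real delaminations do too), so elimination-adjacent neighbor exchanges
  are genuine events, not detector noise.
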