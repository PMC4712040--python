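"""Selective plane projection of a curved epithelial layer.

A dome-shaped monolayer imaged in 3D is accompanied by a sparser decoy
layer at a different depth (in the wing disc: squamous peripodial cells
above the columnar disc proper).  A maximum-intensity projection mixes
the two; the selective projection instead

1. picks, per (x, y) column, the z of maximal (pre-smoothed) intensity —
   high-intensity voxels mostly belong to the target layer;
2. fits a *stiff* smooth surface through the bright-voxel cloud, which
   settles coarsely on the target layer and ignores decoy outliers;
3. discards points farther than a cutoff (in z-slices) from that coarse
   surface;
4. refits a *less stiff* surface through the refined cloud, following
   the target layer's curvature accurately;
5. samples the volume's intensity along the fine surface (max over a
   ±0.5-slice band, linearly interpolated at the band ends).

Stiffness maps to the penalty of a Laplacian-regularized grid smoother
(lambda = stiffness^2).  The smoother's null space contains all affine
surfaces, so planes are reproduced exactly at any stiffness, and its
curvature penalty is non-increasing in stiffness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .params import AnalysisParams

__all__ = [
    "BrightVoxelCloud", "HeightMap", "select_bright_voxels", "fit_surface",
    "filter_by_distance", "selective_projection", "surface_to_mesh",
]


@dataclass
class BrightVoxelCloud:
    """Candidate surface points: columns of (x, y, z, intensity) arrays."""

    points: np.ndarray                  # (N, 4) float: x, y, z, intensity
    shape: tuple[int, int]              # (ny, nx) of the source frame
    selection_rule: str = "per-column argmax after Gaussian pre-smoothing"

    @property
    def is_empty(self) -> bool:
        return self.points.shape[0] == 0


@dataclass
class HeightMap:
    """Fitted surface: z coordinate per (y, x), with the stiffness used."""

    z_of: np.ndarray
    stiffness: float
    valid_mask: np.ndarray

    def total_curvature(self) -> float:
        """Sum of squared discrete Laplacian over the interior (the
        quantity the stiffness penalizes)."""
        lap = (self.z_of[1:-1, :-2] + self.z_of[1:-1, 2:]
               + self.z_of[:-2, 1:-1] + self.z_of[2:, 1:-1]
               - 4 * self.z_of[1:-1, 1:-1])
        return float((lap ** 2).sum())


def select_bright_voxels(frame: np.ndarray,
                         smoothing_radius: float) -> BrightVoxelCloud:
    """Per-(x, y) column, the z of maximal intensity after 3D Gaussian
    pre-smoothing.  Columns with zero maximal intensity are excluded; an
    all-zero volume yields an (flagged) empty cloud."""
    if frame.ndim != 3 or frame.size == 0:
        raise ValueError("select_bright_voxels expects a non-empty 3D volume")
    smoothed = ndi.gaussian_filter(frame.astype(np.float64), smoothing_radius)
    z = np.argmax(smoothed, axis=0)
    inten = np.take_along_axis(smoothed, z[None], axis=0)[0]
    ny, nx = z.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    keep = inten > 0
    pts = np.column_stack([xx[keep], yy[keep], z[keep], inten[keep]]
                          ).astype(np.float64)
    return BrightVoxelCloud(points=pts, shape=(ny, nx))


def fit_surface(cloud: BrightVoxelCloud, stiffness: float,
                grid_step: int = 4) -> HeightMap:
    """Penalized grid smoother through the bright-voxel cloud.

    Observations are averaged on a coarse grid (``grid_step`` px); the
    height field minimizes  sum w (z - obs)^2 + lambda * ||Laplacian z||^2
    with lambda = stiffness^2, then is bilinearly upsampled to the full
    (y, x) grid.  Affine surfaces lie in the penalty's null space, so
    planes are reproduced exactly.
    """
    if cloud.is_empty or cloud.points.shape[0] < 4:
        raise ValueError("fit_surface: need >= 4 points")
    x, y, z = cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]
    if np.linalg.matrix_rank(np.column_stack([x, y, np.ones_like(x)])) < 3:
        raise ValueError("fit_surface: degenerate (collinear) point cloud")
    ny, nx = cloud.shape
    gy = max(2, -(-ny // grid_step))
    gx = max(2, -(-nx // grid_step))
    iy = np.clip((y / grid_step).astype(int), 0, gy - 1)
    ix = np.clip((x / grid_step).astype(int), 0, gx - 1)
    flat = iy * gx + ix
    n = gy * gx
    wsum = np.bincount(flat, minlength=n).astype(np.float64)
    zsum = np.bincount(flat, weights=z, minlength=n)
    obs = np.divide(zsum, wsum, out=np.zeros(n), where=wsum > 0)
    w = (wsum > 0).astype(np.float64)
    lam = float(stiffness) ** 2
    # penalty: second differences along rows and columns (covers edge
    # nodes; any affine/twisted plane lies in the null space)
    rows, cols, vals = [], [], []
    r = 0
    for j in range(gy):
        for i in range(1, gx - 1):
            c = j * gx + i
            for cc, v in ((c, -2.0), (c - 1, 1.0), (c + 1, 1.0)):
                rows.append(r)
                cols.append(cc)
                vals.append(v)
            r += 1
    for j in range(1, gy - 1):
        for i in range(gx):
            c = j * gx + i
            for cc, v in ((c, -2.0), (c - gx, 1.0), (c + gx, 1.0)):
                rows.append(r)
                cols.append(cc)
                vals.append(v)
            r += 1
    L = sparse.csr_matrix((vals, (rows, cols)), shape=(r, n))
    A = sparse.diags(w) + lam * (L.T @ L)
    zg = spsolve(A.tocsc(), w * obs).reshape(gy, gx)
    # bilinear upsample to full resolution (grid nodes at cell centers);
    # linear extrapolation beyond the outermost node centers keeps
    # affine surfaces exact up to the image border
    from scipy.interpolate import RegularGridInterpolator
    interp = RegularGridInterpolator(
        (np.arange(gy), np.arange(gx)), zg,
        method="linear", bounds_error=False, fill_value=None)
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy = (yy - grid_step / 2 + 0.5) / grid_step
    cx = (xx - grid_step / 2 + 0.5) / grid_step
    z_full = interp(np.stack([cy.ravel(), cx.ravel()], axis=1)).reshape(ny, nx)
    valid = np.zeros((ny, nx), dtype=bool)
    valid[:] = True
    return HeightMap(z_of=z_full, stiffness=float(stiffness), valid_mask=valid)


def filter_by_distance(cloud: BrightVoxelCloud, surface: HeightMap,
                       cutoff: float) -> BrightVoxelCloud:
    """Keep exactly the points with |z - z_of(x, y)| <= cutoff (z-slices)."""
    if cloud.is_empty:
        return cloud
    x = cloud.points[:, 0].astype(int)
    y = cloud.points[:, 1].astype(int)
    dist = np.abs(cloud.points[:, 2] - surface.z_of[y, x])
    keep = dist <= cutoff
    return BrightVoxelCloud(points=cloud.points[keep], shape=cloud.shape,
                            selection_rule=cloud.selection_rule
                            + f"; filtered at |dz| <= {cutoff}")


def _sample_band(frame: np.ndarray, z_of: np.ndarray,
                 half_band: float = 0.5) -> np.ndarray:
    """Max intensity over z in [z_of - h, z_of + h], linear interp in z."""
    nz = frame.shape[0]

    def interp(zq: np.ndarray) -> np.ndarray:
        zq = np.clip(zq, 0, nz - 1)
        z0 = np.floor(zq).astype(int)
        z1 = np.minimum(z0 + 1, nz - 1)
        f = zq - z0
        ny, nx = zq.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        return (1 - f) * frame[z0, yy, xx] + f * frame[z1, yy, xx]

    candidates = [interp(z_of - half_band), interp(z_of + half_band)]
    lo = np.ceil(z_of - half_band)
    hi = np.floor(z_of + half_band)
    candidates.append(np.where(lo <= z_of + half_band, interp(lo), -np.inf))
    candidates.append(np.where(hi >= z_of - half_band, interp(hi), -np.inf))
    return np.max(np.stack(candidates), axis=0)


def selective_projection(frame: np.ndarray, params: AnalysisParams,
                         grid_step: int = 4,
                         ) -> tuple[np.ndarray, HeightMap]:
    """Two-step selective projection of one 3D frame.

    Coarse stiff fit -> distance filter -> fine fit -> band sampling.
    Returns the projected 2D image and the fine height map.
    """
    frame = np.asarray(frame, dtype=np.float64)
    cloud = select_bright_voxels(frame, params.smoothing_radius)
    coarse = fit_surface(cloud, params.surf_smoothness_1, grid_step=grid_step)
    refined = filter_by_distance(cloud, coarse,
                                 params.projection_depth_threshold)
    if refined.points.shape[0] < 4:
        refined = cloud  # degenerate filtering; fall back to full cloud
    fine = fit_surface(refined, params.surf_smoothness_2, grid_step=grid_step)
    image = _sample_band(frame, fine.z_of)
    return image, fine


def surface_to_mesh(h: HeightMap, path: str | Path) -> int:
    """Write the height map as an ASCII OBJ triangle mesh.

    One vertex per valid grid node (x, y, z_of); two triangles per grid
    quad whose four corners are all valid.  Returns the vertex count.
    """
    ny, nx = h.z_of.shape
    valid = h.valid_mask
    index = np.full((ny, nx), -1, dtype=int)
    lines = ["# epigraph surface mesh"]
    count = 0
    for j in range(ny):
        for i in range(nx):
            if valid[j, i]:
                count += 1
                index[j, i] = count  # OBJ indices are 1-based
                lines.append(f"v {i} {j} {h.z_of[j, i]:.6f}")
    for j in range(ny - 1):
        for i in range(nx - 1):
            a, b = index[j, i], index[j, i + 1]
            c, d = index[j + 1, i], index[j + 1, i + 1]
            if min(a, b, c, d) > 0:
                lines.append(f"f {a} {b} {d}")
                lines.append(f"f {a} {d} {c}")
    if count == 0:
        warnings.warn("surface_to_mesh: no valid grid nodes; empty mesh")
    Path(path).write_text("\n".join(lines) + "\n")
    return count
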