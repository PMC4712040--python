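"""Image, skeleton, graph and table I/O.

Conventions
-----------
* Stacks are read as one TIFF per time point, 8- or 16-bit; 2D files are
  treated as single-slice volumes.  A file holding more than one time
  point is rejected: one time point must live in exactly one file.
* Skeletons are 8-bit binary TIFF/PNG images, foreground 255 = boundary.
* GraphML export uses fixed attribute names (``frame``, ``cell_id``,
  ``x``, ``y``, ``area``, ``n_neighbors``, ``on_border``; edge ``kind`` in
  {"spatial", "temporal"}) so downstream scripts are stable.
* Axis order is 0-based (z, y, x); z increases away from the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

if TYPE_CHECKING:  # pragma: no cover
    from .graph import SpatioTemporalGraph

__all__ = [
    "ImageStack", "Skeleton", "read_stack", "write_stack",
    "read_skeleton", "write_skeleton", "export_graphml", "export_table",
]

ACCEPTED_EXTENSIONS = {".tif", ".tiff", ".png"}


@dataclass
class ImageStack:
    """4D intensity data as a list of (z, y, x) frames with spacing metadata.

    All frames share shape and dtype; ``dtype_bits`` is 8 or 16.
    ``spacing`` is (dz, dy, dx) in physical units, ``frame_interval`` in
    minutes.
    """

    frames: list[np.ndarray]
    dtype_bits: int = 8
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
        if self.dtype_bits not in (8, 16):
            raise ValueError("dtype_bits must be 8 or 16")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames[0].shape

    def rescaled_frame(self, t: int) -> np.ndarray:
        """Frame *t* as float on the common 0-255 intensity scale."""
        f = self.frames[t].astype(np.float64)
        if self.dtype_bits == 16:
            f = f / 257.0  # 65535 -> 255
        return f


@dataclass
class Skeleton:
    """1-pixel-wide binary cell-boundary image for one frame."""

    image: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        vals = np.unique(self.image)
        if not np.isin(vals, (0, 1, 255)).all():
            raise ValueError(
                f"skeleton image must be binary, found values {vals[:10]}"
            )
        self.image = (self.image > 0)


def read_stack(paths: Sequence[str | Path],
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
               frame_interval: float = 1.0) -> ImageStack:
    """Read an ordered list of single-time-point TIFF/PNG files.

    Each file holds one time point as a 2D image or 3D (z, y, x) volume.
    Files whose leading axis looks like a time series (4D, or explicitly
    multi-point) are rejected, as are mixed shapes or dtypes.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("read_stack: empty file list")
    frames: list[np.ndarray] = []
    for p in paths:
        if p.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(p))
        else:
            from imageio.v3 import imread
            arr = imread(str(p))
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if arr.ndim != 3:
            raise ValueError(
                f"{p}: expected one time point per file (2D image or 3D "
                f"z-stack), got a {arr.ndim}D array; one time point cannot "
                "be distributed across, or share, files"
            )
        frames.append(arr)
    shape0, dtype0 = frames[0].shape, frames[0].dtype
    for p, f in zip(paths, frames):
        if f.shape != shape0:
            raise ValueError(f"{p}: shape {f.shape} differs from {shape0}")
        if f.dtype != dtype0:
            raise ValueError(f"{p}: dtype {f.dtype} differs from {dtype0}")
    if dtype0 == np.uint8:
        bits = 8
    elif dtype0 == np.uint16:
        bits = 16
    else:
        raise ValueError(f"unsupported dtype {dtype0}; stacks must be 8- or 16-bit")
    return ImageStack(frames, dtype_bits=bits, spacing=spacing,
                      frame_interval=frame_interval)


def write_stack(stack: ImageStack, directory: str | Path,
                prefix: str = "frame") -> list[Path]:
    """Write one TIFF per time point; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for t, frame in enumerate(stack.frames):
        p = directory / f"{prefix}_{t:04d}.tif"
        tifffile.imwrite(str(p), frame, photometric="minisblack")
        out.append(p)
    return out


def write_skeleton(s: Skeleton, path: str | Path) -> None:
    """Write an 8-bit binary image: foreground 255, background 0."""
    img = np.where(s.image, 255, 0).astype(np.uint8)
    tifffile.imwrite(str(path), img)


def read_skeleton(path: str | Path, frame_index: int = 0) -> Skeleton:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: skeleton must be a single 2D image")
    return Skeleton(arr, frame_index=frame_index)


def export_graphml(g: "SpatioTemporalGraph", path: str | Path) -> None:
    """Write the spatiotemporal graph as GraphML.

    Nodes are keyed ``"<frame>:<cell_id>"`` and carry frame, cell id,
    centroid, area, neighbor count and border flag; edges carry
    ``kind`` = "spatial" | "temporal".
    """
    import networkx as nx

    out = nx.Graph()
    for node in g.nodes():
        cell = g.cell(*node)
        out.add_node(
            f"{node[0]}:{node[1]}",
            frame=int(node[0]),
            cell_id=int(node[1]),
            x=float(cell.centroid[1]),
            y=float(cell.centroid[0]),
            area=float(cell.area),
            n_neighbors=int(g.degree_spatial(*node)),
            on_border=bool(cell.on_border),
        )
    for (a, b, kind) in g.edges():
        out.add_edge(f"{a[0]}:{a[1]}", f"{b[0]}:{b[1]}", kind=kind)
    nx.write_graphml(out, str(path))


def export_table(rows: Iterable[dict], path: str | Path,
                 format: str = "csv",
                 columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Write per-cell or per-event records as CSV or XLSX.

    ``rows`` is an iterable of flat dicts; an empty iterable yields a
    header-only file (pass ``columns`` to control the header then).
    """
    rows = list(rows)
    df = pd.DataFrame(rows, columns=columns if (columns or not rows) else None)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise ValueError(f"unsupported table format {format!r}; use 'csv' or 'xlsx'")
    return df
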