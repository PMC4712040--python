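"""Validated analysis parameter set and its XML serialization.

Every stage of the pipeline is driven by one :class:`AnalysisParams`
object.  Intensity-valued parameters (``threshold``, ``i_bound_max``) are
interpreted on a 0-255 scale; 16-bit input stacks are linearly rescaled to
that range at load time so one parameter table serves both bit depths.

The XML on-disk names mirror the parameter table shipped with the original
tool (``SmoothingRadius``, ``SurfSmoothness1`` ... ``IBoundMax``) so
existing parameter files remain readable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from lxml import etree

__all__ = ["AnalysisParams", "read_params", "write_params", "WING_PARAMS", "EYE_PARAMS"]

#: sentinel meaning "skip this step" (the parameter table's "#" entries)
SKIP = None

# field name -> XML element name, in fixed serialization order
_XML_NAMES = {
    "smoothing_radius": "SmoothingRadius",
    "surf_smoothness_1": "SurfSmoothness1",
    "projection_depth_threshold": "ProjectionDepthThreshold",
    "surf_smoothness_2": "SurfSmoothness2",
    "enhancement_limit": "enhancement_limit",
    "enhancement_width": "enhancement_width",
    "sigma1": "sigma1",
    "min_cell_size": "mincellsize",
    "threshold": "threshold",
    "merge_criteria": "MergeCriteria",
    "sigma3": "sigma3",
    "large_cell_size_thres": "LargeCellSizeThres",
    "i_bound_max": "IBoundMax",
}
_FIELD_NAMES = {v: k for k, v in _XML_NAMES.items()}


@dataclass(frozen=True)
class AnalysisParams:
    """Parameter set for projection, contrast enhancement and segmentation.

    Parameters
    ----------
    smoothing_radius : float
        Gaussian pre-smoothing radius (pixels) before bright-voxel selection.
    surf_smoothness_1, surf_smoothness_2 : float
        Stiffness of the coarse and fine surface fits (dimensionless).
        The coarse fit must be at least as stiff as the fine one.
    projection_depth_threshold : float
        Distance cutoff (z-slices) separating target-layer voxels from the
        decoy layer after the coarse fit.
    enhancement_limit : float or None
        CLAHE clip limit in (0, 1]; ``None`` skips contrast enhancement.
    enhancement_width : float or None
        CLAHE tile size (pixels); ``None`` skips contrast enhancement.
    sigma1 : float
        Gaussian blur (pixels) before seed generation.
    min_cell_size : float
        Minimum area (pixels^2) for an embryonic region to become a seed.
    threshold : float
        Starting intensity level (0-255) of the rising-threshold sweep.
    merge_criteria : float
        Boundary low-intensity ratio in [0, 1] fusing weakly separated
        embryonic regions.
    sigma3 : float
        Gaussian blur (pixels) before region growing.
    large_cell_size_thres : float
        Regions larger than this (pixels^2) are relabelled background.
    i_bound_max : float
        Post-growth boundaries with mean intensity (0-255) below this fuse
        their flanking regions.
    """

    smoothing_radius: float = 1.0
    surf_smoothness_1: float = 30.0
    projection_depth_threshold: float = 1.2
    surf_smoothness_2: float = 20.0
    enhancement_limit: float | None = 0.02
    enhancement_width: float | None = 30.0
    sigma1: float = 2.0
    min_cell_size: float = 25.0
    threshold: float = 25.0
    merge_criteria: float = 0.15
    sigma3: float = 0.5
    large_cell_size_thres: float = 3000.0
    i_bound_max: float = 30.0

    def __post_init__(self) -> None:
        strictly_positive = [
            "smoothing_radius", "surf_smoothness_1", "projection_depth_threshold",
            "surf_smoothness_2", "sigma1", "min_cell_size", "threshold",
            "sigma3", "large_cell_size_thres", "i_bound_max",
        ]
        for name in strictly_positive:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.enhancement_limit is not None and not 0 < self.enhancement_limit <= 1:
            raise ValueError("enhancement_limit must be in (0, 1] or None")
        if not 0 <= self.merge_criteria <= 1:
            raise ValueError("merge_criteria must be in [0, 1]")
        if self.surf_smoothness_1 < self.surf_smoothness_2:
            raise ValueError(
                "surf_smoothness_1 must be >= surf_smoothness_2 "
                "(the coarse fit is the stiffer one)"
            )


#: defaults for wing-disc-like tissue (dense columnar monolayer)
WING_PARAMS = AnalysisParams()
#: defaults for eye-disc-like tissue
EYE_PARAMS = AnalysisParams(
    sigma1=1.0, min_cell_size=15.0, threshold=20.0, merge_criteria=0.45,
    sigma3=2.0, large_cell_size_thres=4300.0, i_bound_max=20.0,
)


def write_params(params: AnalysisParams, path: str | Path) -> None:
    """Serialize *params* to XML with a stable element order.

    Skipped optional steps are written as ``#`` (the conventional skip
    token of the parameter table).  Serialization is deterministic: the
    same params always produce byte-identical files.
    """
    root = etree.Element("epigraph_params")
    for field_name, xml_name in _XML_NAMES.items():
        el = etree.SubElement(root, xml_name)
        value = getattr(params, field_name)
        el.text = "#" if value is None else repr(float(value))
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )


def read_params(path: str | Path) -> AnalysisParams:
    """Parse a params XML file written by :func:`write_params`.

    Raises
    ------
    ValueError
        If elements are missing or unknown; the message lists the names.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    seen: dict[str, float | None] = {}
    unknown: list[str] = []
    for el in root:
        if not isinstance(el.tag, str):
            continue
        if el.tag not in _FIELD_NAMES:
            unknown.append(el.tag)
            continue
        text = (el.text or "").strip()
        seen[_FIELD_NAMES[el.tag]] = None if text == "#" else float(text)
    missing = [x for f, x in _XML_NAMES.items() if f not in seen]
    if missing or unknown:
        parts = []
        if missing:
            parts.append(f"missing elements: {', '.join(missing)}")
        if unknown:
            parts.append(f"unknown elements: {', '.join(unknown)}")
        raise ValueError("invalid params file: " + "; ".join(parts))
    return AnalysisParams(**seen)
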