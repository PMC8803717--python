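"""ROI placement and the ALPS index.

Four regions of interest — projection and association area per hemisphere at
the level of the lateral ventricle body — are measured on the Dxx/Dyy/Dzz
maps, and the index is the ratio

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

computed per hemisphere (ALPS-R, ALPS-L) and as their bilateral average
(ALPS-Bil). Six ROI patterns share matched centers: large/small (12/8 px)
sphere, cube, and single-slice square.

Even-sided masks have no central voxel; centers therefore sit on half-voxel
coordinates and membership is evaluated on voxel-center distances, keeping
all six patterns symmetric about one shared center. Out-of-plane (z)
distances are scaled by the slice/in-plane spacing ratio so a "12-pixel"
sphere is physically round on anisotropic grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .tensorfit import DiffusivityMaps

__all__ = [
    "MeasurementError",
    "RoiSpec",
    "RoiMask",
    "RoiMeasurement",
    "AlpsResult",
    "make_roi_mask",
    "measure_rois",
    "compute_alps",
    "default_roi_patterns",
    "roi_physical_diameter_mm",
]

HEMISPHERES = ("right", "left")
REGIONS = ("projection", "association")


class MeasurementError(ValueError):
    """ROI measurement failed (empty ROI, missing region, bad index)."""


@dataclass(frozen=True)
class RoiSpec:
    """One measurement ROI: shape, size (pixels), center, placement labels."""

    shape: str  # "sphere" | "cube" | "square"
    size_px: int
    center: tuple[float, float, float]
    hemisphere: str
    region: str
    plane_index: int | None = None  # squares only

    def __post_init__(self):
        if self.shape not in ("sphere", "cube", "square"):
            raise MeasurementError(f"unknown ROI shape {self.shape!r}")
        if self.size_px <= 0:
            raise MeasurementError("size_px must be positive")
        if self.hemisphere not in HEMISPHERES or self.region not in REGIONS:
            raise MeasurementError(f"bad placement {self.hemisphere}/{self.region}")


@dataclass
class RoiMask:
    mask: np.ndarray
    truncated: bool  # True when the shape was clipped by the grid boundary

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class RoiMeasurement:
    dxx: float
    dyy: float
    dzz: float
    voxel_count: int
    truncated: bool


@dataclass
class AlpsResult:
    """Component diffusivities and ALPS indices for one scan and ROI pattern."""

    dxx_proj: dict[str, float]
    dxx_assoc: dict[str, float]
    dyy_proj: dict[str, float]
    dzz_assoc: dict[str, float]
    alps_r: float
    alps_l: float
    alps_bil: float
    roi_voxel_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def roi_physical_diameter_mm(size_px: int, fov_mm: float = 200.0, matrix: int = 256) -> float:
    """Physical ROI diameter: pixel count times the in-plane pixel spacing
    (FOV divided by the reconstructed matrix)."""
    return size_px * fov_mm / matrix


def make_roi_mask(
    spec: RoiSpec,
    grid_shape: tuple[int, int, int],
    pixel_spacing: tuple[float, float, float],
) -> RoiMask:
    """Boolean mask of an ROI on a voxel grid.

    Sphere: voxel centers within Euclidean distance size_px/2 of the center,
    measured in in-plane pixel units with z scaled by the spacing ratio.
    Cube: |delta| <= size_px/2 per axis (same z scaling). Square: the cube
    restricted to one axial slice. Truncation by the grid boundary is
    flagged, not silent.
    """
    cx, cy, cz = spec.center
    if not (0 <= cx < grid_shape[0] and 0 <= cy < grid_shape[1] and 0 <= cz < grid_shape[2]):
        raise MeasurementError(f"ROI center {spec.center} outside grid {grid_shape}")
    sx, sy, sz = pixel_spacing
    zratio = sz / sx
    r = spec.size_px / 2.0

    x = np.arange(grid_shape[0])[:, None, None] - cx
    y = np.arange(grid_shape[1])[None, :, None] - cy
    z = (np.arange(grid_shape[2])[None, None, :] - cz) * zratio

    if spec.shape == "sphere":
        mask = x * x + y * y + z * z <= r * r
    else:
        mask = (np.abs(x) <= r) & (np.abs(y) <= r) & (np.abs(z) <= r)
        if spec.shape == "square":
            plane = spec.plane_index if spec.plane_index is not None else int(round(cz))
            keep = np.zeros(grid_shape[2], dtype=bool)
            keep[plane] = True
            mask = mask & keep[None, None, :]
    mask = np.broadcast_to(mask, grid_shape).copy()

    # truncated iff the ideal extent pokes outside the grid
    lo = np.array([cx - r, cy - r, cz - r / zratio])
    hi = np.array([cx + r, cy + r, cz + r / zratio])
    truncated = bool(np.any(lo < -0.5) or np.any(hi > np.array(grid_shape) - 0.5))
    return RoiMask(mask=mask, truncated=truncated)


def default_roi_patterns() -> dict[str, tuple[str, int]]:
    """The six measurement patterns: (shape, size_px) keyed by name."""
    return {
        "large_sphere": ("sphere", 12),
        "large_cube": ("cube", 12),
        "large_square": ("square", 12),
        "small_sphere": ("sphere", 8),
        "small_cube": ("cube", 8),
        "small_square": ("square", 8),
    }


def build_pattern_rois(
    centers: Mapping[tuple[str, str], tuple[float, float, float]],
    shape: str,
    size_px: int,
) -> list[RoiSpec]:
    """RoiSpecs for all four (hemisphere, region) placements of one pattern."""
    rois = []
    for (hemi, region), c in centers.items():
        plane = int(round(c[2])) if shape == "square" else None
        rois.append(RoiSpec(shape=shape, size_px=size_px, center=tuple(c),
                            hemisphere=hemi, region=region, plane_index=plane))
    return rois


def measure_rois(
    maps: DiffusivityMaps,
    rois: Sequence[RoiSpec],
    pixel_spacing: tuple[float, float, float] | None = None,
) -> dict[tuple[str, str], RoiMeasurement]:
    """ROI-mean Dxx/Dyy/Dzz over each ROI mask intersected with the fit mask."""
    spacing = pixel_spacing or maps.voxel_size_mm or (1.0, 1.0, 1.0)
    grid_shape = maps.dxx.shape
    out: dict[tuple[str, str], RoiMeasurement] = {}
    for roi in rois:
        rm = make_roi_mask(roi, grid_shape, spacing)
        m = rm.mask & maps.fit_mask
        n = int(m.sum())
        if n == 0:
            raise MeasurementError(
                f"ROI {roi.hemisphere}/{roi.region} ({roi.shape} {roi.size_px}px) "
                "has no usable voxels"
            )
        out[(roi.hemisphere, roi.region)] = RoiMeasurement(
            dxx=float(maps.dxx[m].mean()),
            dyy=float(maps.dyy[m].mean()),
            dzz=float(maps.dzz[m].mean()),
            voxel_count=n,
            truncated=rm.truncated,
        )
    return out


def compute_alps(
    measurements: Mapping[tuple[str, str], RoiMeasurement],
    provenance: dict | None = None,
) -> AlpsResult:
    """ALPS indices from the four per-hemisphere ROI measurements.

    Per hemisphere: ALPS = ((Dxx_proj + Dxx_assoc)/2) / ((Dyy_proj +
    Dzz_assoc)/2); the bilateral index is the mean of the two unilateral
    ones. All four component diffusivities must be positive.
    """
    comp: dict[str, dict[str, float]] = {k: {} for k in
                                         ("dxx_proj", "dxx_assoc", "dyy_proj", "dzz_assoc")}
    alps: dict[str, float] = {}
    for hemi in HEMISPHERES:
        try:
            proj = measurements[(hemi, "projection")]
            assoc = measurements[(hemi, "association")]
        except KeyError as exc:
            raise MeasurementError(f"missing ROI measurement for {exc.args[0]}") from exc
        vals = (proj.dxx, assoc.dxx, proj.dyy, assoc.dzz)
        if any(v <= 0 for v in vals):
            raise MeasurementError(
                f"nonpositive component diffusivity in {hemi} hemisphere: {vals}"
            )
        comp["dxx_proj"][hemi] = proj.dxx
        comp["dxx_assoc"][hemi] = assoc.dxx
        comp["dyy_proj"][hemi] = proj.dyy
        comp["dzz_assoc"][hemi] = assoc.dzz
        num = (proj.dxx + assoc.dxx) / 2.0
        den = (proj.dyy + assoc.dzz) / 2.0
        if den <= 0:
            raise MeasurementError("undefined ALPS index: nonpositive denominator")
        alps[hemi] = num / den
    return AlpsResult(
        dxx_proj=comp["dxx_proj"],
        dxx_assoc=comp["dxx_assoc"],
        dyy_proj=comp["dyy_proj"],
        dzz_assoc=comp["dzz_assoc"],
        alps_r=alps["right"],
        alps_l=alps["left"],
        alps_bil=(alps["right"] + alps["left"]) / 2.0,
        roi_voxel_counts={k: v.voxel_count for k, v in measurements.items()},
        provenance=provenance or {},
    )
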