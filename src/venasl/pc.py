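"""2D phase-contrast flow quantification for neck arteries and the SSS.

Velocity is encoded linearly in the image phase up to the VENC limit
(phase of pi corresponds to VENC cm/s).  Vessels are delineated by polygonal
ROIs drawn in pixel coordinates; the cross-sectional area comes from the
polygon geometry (shoelace) while the mean velocity is averaged over the
rasterized pixel set (pixel-center inclusion).  Flow is area x mean
velocity, converted to mL/min.  Bilateral internal carotid measures combine
by summing areas and flows; the combined velocity is flow-weighted, i.e. the
area-weighted mean of the side velocities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from shapely import contains_xy

__all__ = [
    "VesselROI",
    "VesselMetrics",
    "phase_to_velocity",
    "roi_area",
    "rasterize_roi",
    "vessel_flow",
    "combine_ica",
]


@dataclass(frozen=True)
class VesselROI:
    """Polygonal vessel ROI in pixel coordinates.

    ``polygon`` is an ordered vertex sequence (x, y) in pixel units, with the
    convention that pixel (i, j) covers the unit square [i, i+1) x [j, j+1)
    and has its center at (i + 0.5, j + 0.5).  ``pixel_size_mm`` is the
    in-plane pixel edge length in mm.
    """

    name: str
    polygon: tuple[tuple[float, float], ...]
    pixel_size_mm: float = 0.5

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("a vessel ROI needs at least 3 vertices")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")
        object.__setattr__(
            self, "polygon", tuple((float(x), float(y)) for x, y in self.polygon)
        )

    def shapely(self) -> Polygon:
        poly = Polygon(self.polygon)
        if not poly.is_valid or poly.area == 0:
            raise ValueError(f"ROI '{self.name}' is self-intersecting or degenerate")
        return poly


@dataclass(frozen=True)
class VesselMetrics:
    """Cross-sectional area (cm^2), mean velocity (cm/s), flow (mL/min)."""

    name: str
    area: float
    mean_velocity: float
    flow: float


def phase_to_velocity(phase_img: np.ndarray, venc: float) -> np.ndarray:
    """Convert phase (rad) to through-plane velocity (cm/s): v = VENC*phase/pi.

    Phases beyond +/-pi indicate aliasing, which this pipeline does not
    unwrap; such images are rejected rather than silently wrapped.
    """
    phase = np.asarray(phase_img, dtype=float)
    if np.any(np.abs(phase) > np.pi + 1e-12):
        raise ValueError("phase values beyond +/-pi: velocity aliasing is unhandled")
    return venc * phase / np.pi


def roi_area(roi: VesselROI) -> tuple[float, np.ndarray]:
    """Polygon area in cm^2 plus the rasterized pixel mask (boolean, x-by-y).

    The area is the shoelace polygon area scaled by the pixel area; the mask
    marks pixels whose centers fall inside the polygon and is used for
    velocity averaging.
    """
    poly = roi.shapely()
    px_cm = roi.pixel_size_mm / 10.0
    area_cm2 = poly.area * px_cm * px_cm

    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(int(np.floor(minx)), int(np.ceil(maxx)) + 1)
    ys = np.arange(int(np.floor(miny)), int(np.ceil(maxy)) + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    inside = contains_xy(poly, gx + 0.5, gy + 0.5)
    mask = np.zeros((0, 0), dtype=bool)
    if xs.size and ys.size:
        mask = np.zeros((xs[-1] + 1, ys[-1] + 1), dtype=bool)
        mask[gx[inside], gy[inside]] = True
    return area_cm2, mask


def rasterize_roi(roi: VesselROI, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of ``shape`` marking pixels whose centers are in the ROI."""
    poly = roi.shapely()
    gx, gy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return contains_xy(poly, gx + 0.5, gy + 0.5)


def vessel_flow(roi: VesselROI, velocity_img: np.ndarray) -> VesselMetrics:
    """Vessel metrics: area from the polygon, velocity averaged over pixels.

    flow [mL/min] = area [cm^2] * mean velocity [cm/s] * 60 [s/min].
    """
    velocity_img = np.asarray(velocity_img, dtype=float)
    mask = rasterize_roi(roi, velocity_img.shape)
    if not np.any(mask):
        raise ValueError(f"ROI '{roi.name}' rasterizes to an empty pixel set")
    area_cm2, _ = roi_area(roi)
    v_mean = float(velocity_img[mask].mean())
    return VesselMetrics(
        name=roi.name,
        area=area_cm2,
        mean_velocity=v_mean,
        flow=area_cm2 * v_mean * 60.0,
    )


def combine_ica(left: VesselMetrics, right: VesselMetrics) -> VesselMetrics:
    """Bilateral ICA summary: summed area and flow, flow-derived velocity.

    mean_velocity = total flow / (total area * 60), which equals the
    area-weighted mean of the side velocities.
    """
    area = left.area + right.area
    flow = left.flow + right.flow
    if area <= 0:
        raise ValueError("combined ICA area must be positive")
    return VesselMetrics(
        name="ICA", area=area, mean_velocity=flow / (area * 60.0), flow=flow
    )
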