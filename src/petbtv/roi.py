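"""ROI measurements on phantom images: background, TBR, optimal threshold.

For every visually detectable sphere the optimal threshold TS is the
percentage of the maximum intensity in the sphere's central cross section
whose autocontour best recovers the known physical cross-sectional area.
TS is searched exhaustively in 1% steps; an observation is *converged* when
the best area differs from truth by less than a tolerance (10 mm^2 by
default).

All contouring is 2D and transaxial: TS is defined on the maximal cross
section of the target, not on the 3D volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from petbtv.phantom import (
    ImageVolume,
    PhantomSpec,
    SimulatedAcquisition,
    SphereSpec,
    default_background_rois,
)

#: Diameter (mm) of the circular background ROIs.
DEFAULT_BG_ROI_DIAMETER = 17.0

#: Default sigma multiplier of the detectability rule.
DEFAULT_DETECT_K = 3.0

#: 8-connectivity in the transaxial plane.
_STRUCTURE_2D = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BackgroundStats:
    """Mean and SD of the pixels inside the six background ROIs."""

    bg_mean: float
    bg_sd: float
    roi_count: int
    pixel_count: int


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the optimal-threshold search for one sphere observation."""

    ts_percent: int
    measured_area: float
    area_error: float
    converged: bool
    max_intensity: float


@dataclass(frozen=True)
class MeasurementRecord:
    """One (sphere, TBR, ESD, reconstruction) observation.

    ``x1_area`` is the known maximal cross-sectional area A (mm^2),
    ``x2`` = 1 - 1/TBR with the TBR *measured* on the image, and
    ``x3_fwhm`` the transaxial post-filter FWHM (mm).
    """

    scanner_id: str
    sphere_id: str
    x1_area: float
    tbr_nominal: float
    tbr_measured: float
    x2: float
    x3_fwhm: float
    esd: float
    em_iterations: int
    ts: int
    converged: bool
    extras: Mapping[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.x2 < 1.0):
            raise ValueError("x2 = 1 - 1/TBR must lie in [0, 1)")
        if abs(self.x2 - (1.0 - 1.0 / self.tbr_measured)) > 1e-9:
            raise ValueError("x2 inconsistent with tbr_measured")
        if not (1 <= self.ts <= 100):
            raise ValueError("ts must lie in [1, 100]")


def _circle_pixels(
    img: ImageVolume,
    slice_index: int,
    center_xy: Sequence[float],
    diameter_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of pixels whose center lies inside a transaxial circle."""
    grid = img.grid
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    r = diameter_mm / 2.0
    dx2 = (xs - center_xy[0]) ** 2
    dy2 = (ys - center_xy[1]) ** 2
    inside = dx2[:, None] + dy2[None, :] <= r**2
    return np.nonzero(inside)


def _roi_in_image(
    img: ImageVolume, center_xy: Sequence[float], diameter_mm: float
) -> bool:
    grid = img.grid
    r = diameter_mm / 2.0
    for axis in range(2):
        lo = grid.origin[axis] - grid.voxel_size[axis] / 2.0
        hi = lo + grid.shape[axis] * grid.voxel_size[axis]
        if center_xy[axis] - r < lo or center_xy[axis] + r > hi:
            return False
    return True


def background_mean(
    img: ImageVolume,
    roi_centers: Sequence[Sequence[float]] | None = None,
    slice_index: int | None = None,
    diameter_mm: float = DEFAULT_BG_ROI_DIAMETER,
    truth: PhantomSpec | None = None,
) -> BackgroundStats:
    """Mean background intensity (BG) over circular ROIs.

    Six 17 mm-diameter ROIs are placed in the background surrounding the
    spheres; the mean over the union of their pixels is the background value
    BG and the SD over the same pixels the background noise.  ROI centers
    may be (x, y, z) world points, in which case each ROI is evaluated on
    the slice closest to its own z, or (x, y) pairs evaluated on
    ``slice_index``.

    When the ground-truth phantom is supplied, any ROI that intersects a
    sphere in its plane is an error.
    """
    if roi_centers is None:
        roi_centers = default_background_rois()
    values = []
    for center in roi_centers:
        if len(center) >= 3:
            k = img.slice_index_at(center[2])
        elif slice_index is not None:
            k = slice_index
        else:
            raise ValueError("2D ROI centers require slice_index")
        if not _roi_in_image(img, center[:2], diameter_mm):
            raise ValueError(f"background ROI at {tuple(center)} falls outside image")
        if truth is not None:
            z = img.grid.axis_coords(2)[k]
            r_roi = diameter_mm / 2.0
            for sphere in truth.spheres:
                dz = z - sphere.center[2]
                if abs(dz) >= sphere.radius:
                    continue
                r_slice = np.sqrt(sphere.radius**2 - dz**2)
                d = np.hypot(
                    center[0] - sphere.center[0], center[1] - sphere.center[1]
                )
                if d < r_roi + r_slice:
                    raise ValueError(
                        f"background ROI at {tuple(center)} overlaps "
                        f"sphere {sphere.label}"
                    )
        ii, jj = _circle_pixels(img, k, center[:2], diameter_mm)
        values.append(img.transaxial_slice(k)[ii, jj])
    pixels = np.concatenate(values)
    return BackgroundStats(
        bg_mean=float(pixels.mean()),
        bg_sd=float(pixels.std(ddof=0)),
        roi_count=len(roi_centers),
        pixel_count=int(pixels.size),
    )


def _sphere_roi_max(
    img: ImageVolume, sphere: SphereSpec, margin_pixels: float = 2.0
) -> float:
    """Maximum pixel in a circle encircling the sphere's central cross
    section (diameter ID plus a margin of ``margin_pixels`` pixels)."""
    k = img.slice_index_at(sphere.center[2])
    diameter = sphere.internal_diameter + 2.0 * margin_pixels * img.voxel_size[0]
    ii, jj = _circle_pixels(img, k, sphere.center[:2], diameter)
    if ii.size == 0:
        raise ValueError(f"encircling ROI of sphere {sphere.label} is empty")
    return float(img.transaxial_slice(k)[ii, jj].max())


def measured_tbr(
    img: ImageVolume,
    sphere: SphereSpec,
    bg: BackgroundStats,
    margin_pixels: float = 2.0,
) -> float:
    """Measured target-to-background ratio.

    The maximum pixel in an ROI encircling the target cross section at the
    sphere's central slice divided by the mean background intensity.
    Because of partial-volume effects this is below the nominal activity
    ratio for spheres small relative to the system resolution.
    """
    if bg.bg_mean <= 0:
        raise ValueError("background mean must be positive")
    return _sphere_roi_max(img, sphere, margin_pixels) / bg.bg_mean


def detectable(
    img: ImageVolume,
    sphere: SphereSpec,
    bg: BackgroundStats,
    k_sigma: float = DEFAULT_DETECT_K,
    margin_pixels: float = 2.0,
) -> bool:
    """Objective stand-in for visual detectability.

    A sphere counts as detectable when its ROI maximum exceeds the
    background mean by more than ``k_sigma`` background SDs.
    """
    peak = _sphere_roi_max(img, sphere, margin_pixels)
    return peak > bg.bg_mean + k_sigma * bg.bg_sd


def _window_bounds(
    shape: Sequence[int],
    center_index: Sequence[int],
    pixel_size: Sequence[float],
    window_half_mm: float,
) -> tuple[tuple[int, int], tuple[int, int]]:
    hw_i = max(int(round(window_half_mm / pixel_size[0])), 1)
    hw_j = max(int(round(window_half_mm / pixel_size[1])), 1)
    i0 = max(center_index[0] - hw_i, 0)
    i1 = min(center_index[0] + hw_i + 1, shape[0])
    j0 = max(center_index[1] - hw_j, 0)
    j1 = min(center_index[1] + hw_j + 1, shape[1])
    return (i0, i1), (j0, j1)


def autocontour_area(
    slice2d: np.ndarray,
    ts_percent: float,
    center_index: Sequence[int],
    pixel_size: Sequence[float],
    window_half_mm: float,
) -> tuple[np.ndarray, float]:
    """Autocontour a cross section at a threshold and measure its area.

    Pixels of the square window around ``center_index`` at or above
    ``ts_percent`` percent of the window maximum are labelled with
    8-connectivity; the contour is the connected component containing the
    window maximum.  The area is the pixel count times the pixel area (no
    sub-pixel polygonization).

    Returns the boolean mask (full slice size) and the area in mm^2.
    """
    if not (1 <= ts_percent <= 100):
        raise ValueError("ts_percent must lie in [1, 100]")
    (i0, i1), (j0, j1) = _window_bounds(
        slice2d.shape, center_index, pixel_size, window_half_mm
    )
    window = slice2d[i0:i1, j0:j1]
    if window.size == 0:
        raise ValueError("contour window is empty")
    flat_max = int(np.argmax(window))
    mi, mj = np.unravel_index(flat_max, window.shape)
    vmax = window[mi, mj]
    threshold = ts_percent / 100.0 * vmax
    above = window >= threshold
    labels, _ = ndimage.label(above, structure=_STRUCTURE_2D)
    component = labels == labels[mi, mj]
    mask = np.zeros_like(slice2d, dtype=bool)
    mask[i0:i1, j0:j1] = component
    area = float(component.sum()) * pixel_size[0] * pixel_size[1]
    return mask, area


def find_optimal_ts(
    slice2d: np.ndarray,
    sphere: SphereSpec,
    center_index: Sequence[int],
    pixel_size: Sequence[float],
    tolerance: float = 10.0,
    step: int = 1,
    window_margin_mm: float = 12.0,
) -> ThresholdResult:
    """Exhaustive search for the threshold that recovers the true area.

    Thresholds from 1% to 100% of the cross-section maximum are scanned in
    ``step``-percent increments; the TS minimizing the absolute area error
    versus the sphere's known cross-sectional area is returned, ties broken
    toward the larger TS.  The observation converged when the best error is
    below ``tolerance`` (mm^2).
    """
    window_half = sphere.radius + window_margin_mm
    (i0, i1), (j0, j1) = _window_bounds(
        slice2d.shape, center_index, pixel_size, window_half
    )
    if slice2d[i0:i1, j0:j1].size == 0:
        raise ValueError("contour window is empty")
    vmax = float(slice2d[i0:i1, j0:j1].max())
    candidates = np.arange(step, 101, step, dtype=int)
    best: tuple[float, int, float] | None = None  # (|err|, ts, area)
    for ts in candidates:
        _, area = autocontour_area(
            slice2d, int(ts), center_index, pixel_size, window_half
        )
        if area <= 0:
            continue
        err = abs(area - sphere.true_area)
        if best is None or err < best[0] or (err == best[0] and ts > best[1]):
            best = (err, int(ts), area)
    if best is None:
        raise ValueError("no threshold produced a non-empty contour")
    err, ts, area = best
    return ThresholdResult(
        ts_percent=ts,
        measured_area=area,
        area_error=area - sphere.true_area,
        converged=err < tolerance,
        max_intensity=vmax,
    )


def build_records(
    dataset: Iterable[SimulatedAcquisition],
    scanner_id: str = "SIM",
    bg_roi_centers: Sequence[Sequence[float]] | None = None,
    tolerance: float = 10.0,
    step: int = 1,
    detect_k: float = DEFAULT_DETECT_K,
    window_margin_mm: float = 12.0,
) -> tuple[list[MeasurementRecord], int]:
    """Measure TS and predictors for every detectable sphere of a dataset.

    Returns the records plus the number of sphere observations skipped as
    undetectable — the bookkeeping that explains the gap between the
    theoretical and the realized number of data points.
    """
    records: list[MeasurementRecord] = []
    skipped = 0
    for acq in dataset:
        img = acq.image
        bg = background_mean(img, bg_roi_centers, truth=acq.phantom)
        for sphere in acq.phantom.spheres:
            if not detectable(img, sphere, bg, k_sigma=detect_k):
                skipped += 1
                continue
            tbr_m = measured_tbr(img, sphere, bg)
            k = img.slice_index_at(sphere.center[2])
            ci = img.grid.world_to_index(sphere.center)
            result = find_optimal_ts(
                img.transaxial_slice(k),
                sphere,
                (ci[0], ci[1]),
                img.voxel_size[:2],
                tolerance=tolerance,
                step=step,
                window_margin_mm=window_margin_mm,
            )
            records.append(
                MeasurementRecord(
                    scanner_id=scanner_id,
                    sphere_id=sphere.label,
                    x1_area=sphere.true_area,
                    tbr_nominal=acq.phantom.tbr_nominal,
                    tbr_measured=tbr_m,
                    x2=1.0 - 1.0 / tbr_m,
                    x3_fwhm=acq.recon.transaxial_fwhm,
                    esd=acq.acquisition.esd,
                    em_iterations=acq.recon.em_iterations,
                    ts=result.ts_percent,
                    converged=result.converged,
                    extras=dict(acq.recon.extras),
                )
            )
    return records, skipped
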