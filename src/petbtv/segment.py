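"""Apply a calibrated threshold model to delineate a BTV on an image.

Given a reconstructed volume, a lesion window, the calibration model for
the scanner and the transaxial filter FWHM actually used at reconstruction,
the workflow is: measure the background from operator-placed ROIs, measure
the lesion TBR, predict the optimal threshold TS, and keep the connected
component above TS% of the lesion maximum.  Models whose equation contains
the cross-sectional area A (unknown before segmenting) are solved by
fixed-point iteration starting from the area of a 50% contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from petbtv.calibration import CalibrationModel, predict_ts
from petbtv.phantom import ImageVolume
from petbtv.roi import BackgroundStats, background_mean

#: Minimum measured TBR considered segmentable.
MIN_CONTRAST = 1.2

#: TBR above the calibrated protocol range triggers a warning.
MAX_CALIBRATED_TBR = 70.0

#: Cross-section area (mm^2) below the calibrated range triggers a warning.
MIN_CALIBRATED_AREA = 133.0

_STRUCTURE_3D = np.ones((3, 3, 3), dtype=bool)

Window = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class SegmentationResult:
    """A delineated biological target volume."""

    ts_applied: int
    measured_tbr: float
    mask: np.ndarray  # boolean, full volume shape
    slice_areas: Mapping[int, float]  # mm^2 per transaxial slice index
    volume_ml: float
    model_id: str
    background: BackgroundStats
    converged: bool = True
    iterations: int = 1

    @property
    def max_cross_section_area(self) -> float:
        return max(self.slice_areas.values()) if self.slice_areas else 0.0


def _check_window(img: ImageVolume, window: Window) -> None:
    for axis, (lo, hi) in enumerate(window):
        if not (0 <= lo < hi <= img.intensities.shape[axis]):
            raise ValueError(f"lesion window exceeds image bounds on axis {axis}")


def _contour_at_ts(
    img: ImageVolume, window: Window, ts_percent: int
) -> tuple[np.ndarray, dict[int, float], float]:
    """Threshold the window at ts% of its max; keep the component holding
    the max; return (full-volume mask, per-slice areas, volume in mL)."""
    (x0, x1), (y0, y1), (z0, z1) = window
    sub = img.intensities[x0:x1, y0:y1, z0:z1]
    if sub.size == 0:
        raise ValueError("lesion window is empty")
    peak_idx = np.unravel_index(int(np.argmax(sub)), sub.shape)
    threshold = ts_percent / 100.0 * sub[peak_idx]
    labels, _ = ndimage.label(sub >= threshold, structure=_STRUCTURE_3D)
    component = labels == labels[peak_idx]
    mask = np.zeros(img.intensities.shape, dtype=bool)
    mask[x0:x1, y0:y1, z0:z1] = component
    pixel_area = img.pixel_area
    areas = {
        z0 + k: float(component[:, :, k].sum()) * pixel_area
        for k in range(component.shape[2])
        if component[:, :, k].any()
    }
    volume_ml = sum(areas.values()) * img.voxel_size[2] / 1000.0
    return mask, areas, volume_ml


def _measure_contrast(
    img: ImageVolume,
    window: Window,
    bg_rois: Sequence[Sequence[float]] | None,
) -> tuple[float, BackgroundStats]:
    bg = background_mean(img, bg_rois)
    if bg.bg_mean <= 0:
        raise ValueError("background mean must be positive")
    (x0, x1), (y0, y1), (z0, z1) = window
    sub = img.intensities[x0:x1, y0:y1, z0:z1]
    if sub.size == 0:
        raise ValueError("lesion window is empty")
    tbr = float(sub.max()) / bg.bg_mean
    if tbr < MIN_CONTRAST:
        raise ValueError(
            f"insufficient contrast: measured TBR {tbr:.2f} < {MIN_CONTRAST}"
        )
    if tbr > MAX_CALIBRATED_TBR:
        warnings.warn(
            f"measured TBR {tbr:.1f} exceeds the calibrated range "
            f"(<= {MAX_CALIBRATED_TBR}); extrapolating",
            stacklevel=3,
        )
    return tbr, bg


def delineate_btv(
    img: ImageVolume,
    lesion_window: Window,
    model: CalibrationModel,
    fwhm_used: float,
    bg_rois: Sequence[Sequence[float]] | None = None,
) -> SegmentationResult:
    """Delineate a BTV with an area-free calibration model.

    ``fwhm_used`` is the transaxial post-filter FWHM actually applied at
    reconstruction — a known input, never estimated from the image.  Models
    containing an area term need :func:`area_model_iteration` instead.
    """
    _check_window(img, lesion_window)
    if "area" in model.coefficients:
        raise ValueError(
            "model contains a cross-sectional-area term; use area_model_iteration"
        )
    tbr, bg = _measure_contrast(img, lesion_window, bg_rois)
    ts = predict_ts(model, tbr=tbr, fwhm=fwhm_used).percent
    mask, areas, volume = _contour_at_ts(img, lesion_window, ts)
    return SegmentationResult(
        ts_applied=ts,
        measured_tbr=tbr,
        mask=mask,
        slice_areas=areas,
        volume_ml=volume,
        model_id=model.scanner_model,
        background=bg,
    )


def area_model_iteration(
    img: ImageVolume,
    lesion_window: Window,
    model: CalibrationModel,
    fwhm_used: float,
    bg_rois: Sequence[Sequence[float]] | None = None,
    max_iter: int = 20,
    tol: float = 1.0,
) -> SegmentationResult:
    """Delineate a BTV with a model that includes the area term.

    The area entering the equation is the contour's own maximal cross
    section, so the threshold is found by fixed-point iteration: start from
    the area of a 50% contour, alternate predict-threshold / contour until
    the area changes by less than ``tol`` mm^2 or ``max_iter`` is reached
    (the best iterate is then returned flagged non-converged).  For models
    without an area term this reduces to a single contouring pass.
    """
    _check_window(img, lesion_window)
    tbr, bg = _measure_contrast(img, lesion_window, bg_rois)

    if "area" not in model.coefficients:
        ts = predict_ts(model, tbr=tbr, fwhm=fwhm_used).percent
        mask, areas, volume = _contour_at_ts(img, lesion_window, ts)
        return SegmentationResult(
            ts_applied=ts,
            measured_tbr=tbr,
            mask=mask,
            slice_areas=areas,
            volume_ml=volume,
            model_id=model.scanner_model,
            background=bg,
        )

    _, areas, _ = _contour_at_ts(img, lesion_window, 50)
    area = max(areas.values())
    best: tuple[float, SegmentationResult] | None = None
    for iteration in range(1, max_iter + 1):
        if area < MIN_CALIBRATED_AREA:
            warnings.warn(
                f"cross-section area {area:.0f} mm^2 below the calibrated "
                f"range (> {MIN_CALIBRATED_AREA:.0f} mm^2)",
                stacklevel=2,
            )
        ts = predict_ts(model, tbr=tbr, fwhm=fwhm_used, area=area).percent
        mask, slice_areas, volume = _contour_at_ts(img, lesion_window, ts)
        new_area = max(slice_areas.values())
        delta = abs(new_area - area)
        result = SegmentationResult(
            ts_applied=ts,
            measured_tbr=tbr,
            mask=mask,
            slice_areas=slice_areas,
            volume_ml=volume,
            model_id=model.scanner_model,
            background=bg,
            converged=delta < tol,
            iterations=iteration,
        )
        if best is None or delta < best[0]:
            best = (delta, result)
        if delta < tol:
            return result
        area = new_area
    return best[1]
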