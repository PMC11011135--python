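"""Image- and delay-quality metrics: FWHM, CNR, PSNR, location and
delay errors.

Conventions:

* CNR = 20·log10(|μ_out − μ_in| / sqrt(σ_out² + σ_in²)) over
  linear-scale pixels.  The absolute difference keeps the metric
  real-valued when the target is brighter than the background (the
  common case for a hyperechoic point target).
* PSNR = 10·log10(peak² / MSE) over dB-domain pixels with
  peak = the display dynamic-range span (60 dB by default).
* Location error is the signed depth difference (ground truth −
  estimate), in mm.
* Delay error sums the per-scanline absolute differences between an
  estimated and a ground-truth delay curve (samples); the mean error
  is that total divided by the number of scanlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beamform import BModeImage
from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "MetricsReport",
    "profile_fwhm",
    "fwhm",
    "cnr",
    "psnr",
    "location_error",
    "delay_error",
    "disc_mask",
    "annulus_mask",
]


@dataclass
class MetricsReport:
    """One evaluation row (Table-style): resolution, contrast, fidelity."""

    lateral_fwhm_mm: float
    axial_fwhm_mm: float
    cnr_db: float
    psnr_db: float
    location_error_mm: float
    delay_total_error_samples: float
    delay_mean_error_samples: float

    HEADER = (
        "lateral_fwhm_mm,axial_fwhm_mm,cnr_db,psnr_db,"
        "location_error_mm,delay_total_error_samples,delay_mean_error_samples"
    )

    def to_row(self) -> str:
        vals = (
            self.lateral_fwhm_mm,
            self.axial_fwhm_mm,
            self.cnr_db,
            self.psnr_db,
            self.location_error_mm,
            self.delay_total_error_samples,
            self.delay_mean_error_samples,
        )
        return ",".join(f"{v:.6g}" for v in vals)


def profile_fwhm(values: np.ndarray, coords_mm: np.ndarray) -> float:
    """Full width at half maximum of a 1-D linear-scale profile, in mm.

    The two half-maximum crossings on either side of the peak are
    located by linear interpolation between samples.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(coords_mm, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("profile and coordinates must be matching 1-D arrays")
    k = int(np.argmax(y))
    half = y[k] / 2.0
    if y[k] <= 0:
        raise UndefinedMetricError("profile has no positive peak")

    def _cross(idx_range):
        prev = k
        for i in idx_range:
            if y[i] < half:
                # interpolate between i and prev
                t = (half - y[i]) / (y[prev] - y[i])
                return x[i] + t * (x[prev] - x[i])
            prev = i
        raise UndefinedMetricError("profile never falls below half maximum")

    left = _cross(range(k - 1, -1, -1))
    right = _cross(range(k + 1, len(y)))
    return float(abs(right - left))


def fwhm(image: BModeImage, point_xz_mm, axis: str = "lateral") -> float:
    """FWHM (mm) of the envelope profile through the peak nearest a point.

    The profile runs through the brightest pixel in a small
    neighborhood of ``point_xz_mm`` (±3 mm), along ``"lateral"`` or
    ``"axial"``; the image's linear-scale pixels are used.
    """
    px, pz = float(point_xz_mm[0]), float(point_xz_mm[1])
    lin = image.linear
    near_z = np.abs(image.depth_mm - pz) <= 3.0
    near_x = np.abs(image.lateral_mm - px) <= 3.0
    if not (near_z.any() and near_x.any()):
        raise ValidationError("point lies outside the image")
    sub = np.where(near_z[:, None] & near_x[None, :], lin, -np.inf)
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    if axis == "lateral":
        return profile_fwhm(lin[i, :], image.lateral_mm)
    if axis == "axial":
        return profile_fwhm(lin[:, j], image.depth_mm)
    raise ValidationError(f"unknown axis {axis!r}")


def cnr(image_linear: np.ndarray, inner_roi, outer_roi) -> float:
    """Contrast-to-noise ratio (dB) between inner and outer regions."""
    img = np.asarray(image_linear, dtype=float)
    inner = img[inner_roi]
    outer = img[outer_roi]
    if inner.size == 0 or outer.size == 0:
        raise ValidationError("both ROIs must be non-empty")
    denom = np.sqrt(inner.var() + outer.var())
    if denom == 0:
        raise UndefinedMetricError("zero variance in both ROIs")
    diff = abs(outer.mean() - inner.mean())
    if diff == 0:
        return -np.inf  # undefined-contrast sentinel
    return float(20.0 * np.log10(diff / denom))


def psnr(image_db: np.ndarray, reference_db: np.ndarray, peak: float = 60.0) -> float:
    """Peak signal-to-noise ratio (dB) between two dB-domain images."""
    a = np.asarray(image_db, dtype=float)
    b = np.asarray(reference_db, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("image shapes differ")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return np.inf
    return float(10.0 * np.log10(peak**2 / mse))


def location_error(gt_z_mm: float, est_z_mm: float) -> float:
    """Signed axial location error: ground truth − estimate (mm)."""
    return float(gt_z_mm) - float(est_z_mm)


def delay_error(estimated, ground_truth, mode: str = "abs"):
    """(total, mean) delay-curve error in samples.

    ``abs`` sums per-scanline absolute differences; ``var`` sums
    squared differences instead (both divided by the number of
    scanlines for the mean).
    """
    est = np.asarray(estimated, dtype=float)
    gt = np.asarray(ground_truth, dtype=float)
    if est.shape != gt.shape:
        raise ValidationError("delay curves must have equal length")
    diff = est - gt
    if mode == "abs":
        total = float(np.sum(np.abs(diff)))
    elif mode == "var":
        total = float(np.sum(diff**2))
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return total, total / est.size


def disc_mask(image: BModeImage, center_xz_mm, radius_mm: float) -> np.ndarray:
    """Boolean pixel mask of a disc in image coordinates."""
    cx, cz = float(center_xz_mm[0]), float(center_xz_mm[1])
    dz = image.depth_mm[:, None] - cz
    dx = image.lateral_mm[None, :] - cx
    return dz**2 + dx**2 <= radius_mm**2


def annulus_mask(image: BModeImage, center_xz_mm, r_in_mm: float, r_out_mm: float):
    """Boolean pixel mask of an annulus (background ring) around a point."""
    return disc_mask(image, center_xz_mm, r_out_mm) & ~disc_mask(
        image, center_xz_mm, r_in_mm
    )
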