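"""B-mode reconstruction: APR-delayed summation and geometry-aware DAS.

Both beamformers share the same post-processing: the delayed channels
of each scanline are summed into a single trace, envelope-detected
(analytic-signal magnitude) and log-compressed to a −60..0 dB display
range.  The image grid is one column per scanline and one row per RF
sample depth (z = c·(t0 + n/fs)/2); no scan conversion is applied, so
columns follow scanline axes.

The APR summation is fixed-focus by construction: a single integer
delay per column, constant along depth.  The DAS reference defaults to
dynamic receive focusing (delays recomputed per depth sample from the
known element positions) and is the ground-truth image the APR result
is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .apr import DelayCurve, apply_delays, oracle_delays
from .errors import DegenerateInputError, ValidationError
from .geometry import ArrayGeometry
from .simulate import RFChannelData, _gather_columns

__all__ = ["BModeImage", "envelope", "log_compress", "beamform_apr", "beamform_das"]

DEFAULT_FLOOR_DB = -60.0


@dataclass
class BModeImage:
    """Log-compressed image [depth × lateral] with pixel geometry."""

    pixels_db: np.ndarray
    depth_mm: np.ndarray
    lateral_mm: np.ndarray
    floor_db: float
    provenance: str  # 'apr' | 'das_groundtruth' | 'no_delay'

    @property
    def pixel_dz(self) -> float:
        return float(np.median(np.diff(self.depth_mm)))

    @property
    def pixel_dx(self) -> float:
        return float(np.median(np.diff(self.lateral_mm)))

    @property
    def linear(self) -> np.ndarray:
        """Envelope image on a linear scale (max = 1)."""
        return 10.0 ** (self.pixels_db / 20.0)

    def argmax_location(self) -> tuple[float, float]:
        """(depth_mm, lateral_mm) of the brightest pixel."""
        i, j = np.unravel_index(np.argmax(self.pixels_db), self.pixels_db.shape)
        return float(self.depth_mm[i]), float(self.lateral_mm[j])


def envelope(trace: np.ndarray, axis: int = 0) -> np.ndarray:
    """Analytic-signal magnitude of an RF trace (length unchanged)."""
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValidationError("envelope requires finite input")
    if not trace.any():
        return np.zeros_like(trace)
    return np.abs(hilbert(trace, axis=axis))


def log_compress(image_linear: np.ndarray, floor_db: float = DEFAULT_FLOOR_DB):
    """20·log10(x / max), clipped below at ``floor_db`` (max maps to 0 dB)."""
    image_linear = np.asarray(image_linear, dtype=float)
    peak = image_linear.max() if image_linear.size else 0.0
    if peak <= 0:
        raise DegenerateInputError("log compression needs a positive maximum")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(image_linear / peak)
    return np.clip(db, floor_db, None)


def _lateral_axis(rf: RFChannelData, assumed_pitch: float = 1.0) -> np.ndarray:
    """Lateral coordinate of each scanline column (mm).

    Uses the transmit element's lateral position when a geometry is
    attached; shape-unknown data fall back to a centered uniform grid
    at ``assumed_pitch`` (labeling only — APR itself never uses it).
    """
    if rf.scanline_x is not None:
        return rf.scanline_x.astype(float)
    s = np.arange(rf.n_scanlines, dtype=float)
    return (s - (rf.n_scanlines - 1) / 2.0) * assumed_pitch


def beamform_apr(
    rf: RFChannelData,
    delay_curve: DelayCurve,
    floor_db: float = DEFAULT_FLOOR_DB,
    assumed_pitch: float = 1.0,
) -> BModeImage:
    """Fixed-focus summation image from APR (or oracle) delays.

    Applies the total integer delays, sums across the element
    dimension, envelope-detects each scanline trace and log-compresses.
    """
    delayed = apply_delays(rf, delay_curve)
    summed = delayed.data.sum(axis=1)  # (n_samples, n_scanlines)
    if not summed.any():
        raise DegenerateInputError("beamforming produced an all-zero image")
    env = np.abs(hilbert(summed, axis=0))
    return BModeImage(
        pixels_db=log_compress(env, floor_db),
        depth_mm=rf.depth_axis_mm,
        lateral_mm=_lateral_axis(rf, assumed_pitch),
        floor_db=floor_db,
        provenance="apr",
    )


def beamform_das(
    rf: RFChannelData,
    geometry: ArrayGeometry | None = None,
    focus_mode: str = "dynamic",
    focal_depth_mm: float | None = None,
    floor_db: float = DEFAULT_FLOOR_DB,
) -> BModeImage:
    """Geometry-aware delay-and-sum reference (ground truth) image.

    ``dynamic`` recomputes exact two-way ToF delays for every focal
    point along each scanline's axis (the vertical line through the
    transmit element) and sums the linearly interpolated channels.
    ``fixed`` applies one integer geometric delay per column, computed
    for the focal point at ``focal_depth_mm`` on the array axis — this
    path is identical to :func:`beamform_apr` fed with
    :func:`flexbeam.apr.oracle_delays`.

    No apodization and no aperture growth: the full receive aperture
    contributes at every depth.
    """
    geometry = geometry if geometry is not None else rf.geometry
    if geometry is None:
        raise ValidationError("DAS requires a known array geometry")

    if focus_mode == "fixed":
        if focal_depth_mm is None:
            raise ValidationError("fixed focus requires focal_depth_mm")
        curve = oracle_delays(
            geometry,
            (0.0, focal_depth_mm),
            fs=rf.fs,
            sound_speed=rf.sound_speed,
            t0=rf.t0,
            tx_map=rf.tx_element_of_scanline,
        )
        img = beamform_apr(rf, curve, floor_db)
        img.provenance = "das_groundtruth"
        return img
    if focus_mode != "dynamic":
        raise ValidationError(f"unknown focus_mode {focus_mode!r}")

    N, E, S = rf.data.shape
    c_mm = rf.sound_speed * 1e3
    z_grid = np.maximum(rf.depth_axis_mm, 1e-9)
    axis_x = (
        rf.scanline_x
        if rf.scanline_x is not None
        else geometry.element_x[rf.tx_element_of_scanline].astype(float)
    )
    summed = np.empty((N, S))
    for s in range(S):
        e = rf.tx_element_of_scanline[s]
        d = np.hypot(
            axis_x[s] - geometry.element_x[None, :],
            z_grid[:, None] - geometry.element_z[None, :],
        )  # (N, E) mm
        tof = (d[:, e][:, None] + d) / c_mm
        coords = (tof - rf.t0) * rf.fs
        summed[:, s] = _gather_columns(rf.data[:, :, s], coords, "bandlimited").sum(
            axis=1
        )
    if not summed.any():
        raise DegenerateInputError("beamforming produced an all-zero image")
    env = np.abs(hilbert(summed, axis=0))
    return BModeImage(
        pixels_db=log_compress(env, floor_db),
        depth_mm=rf.depth_axis_mm,
        lateral_mm=axis_x.astype(float),
        floor_db=floor_db,
        provenance="das_groundtruth",
    )
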