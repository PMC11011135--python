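"""Normalization, depth gating and smoothing of RF data and delay curves.

The preprocessing goal is to make the marker peak responses dominant
before peak alignment: global normalization scales the whole tensor so
its maximum magnitude is 1; gated normalization additionally rescales
by the maximum inside a depth band around the marker (9–24 mm by
default, matching a marker structure ~17 mm tall sitting on the skin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .errors import DegenerateInputError, ValidationError
from .simulate import RFChannelData

__all__ = [
    "GateWindow",
    "DEFAULT_GATE",
    "normalize_global",
    "normalize_gated",
    "smooth_trace",
    "smooth_delay_curve",
    "depth_to_sample",
]


def depth_to_sample(z_mm, fs: float, sound_speed: float, t0: float = 0.0):
    """Pulse-echo depth (mm) → sample index: n = round((2z/c − t0)·fs)."""
    t = 2.0 * np.asarray(z_mm, dtype=float) / (sound_speed * 1e3)
    return np.rint((t - t0) * fs).astype(int)


@dataclass(frozen=True)
class GateWindow:
    """Axial depth band [z_min, z_max] in mm (pulse-echo convention)."""

    z_min: float
    z_max: float

    def __post_init__(self):
        if not (0 <= self.z_min < self.z_max):
            raise ValidationError("gate requires 0 <= z_min < z_max")

    def sample_slice(self, rf: RFChannelData) -> slice:
        """Sample-index slice of this depth band within ``rf``'s record."""
        n0 = int(depth_to_sample(self.z_min, rf.fs, rf.sound_speed, rf.t0))
        n1 = int(depth_to_sample(self.z_max, rf.fs, rf.sound_speed, rf.t0)) + 1
        n0 = max(n0, 0)
        n1 = min(n1, rf.n_samples)
        if n0 >= n1:
            raise ValidationError(
                f"gate [{self.z_min}, {self.z_max}] mm falls outside the record"
            )
        return slice(n0, n1)


#: The marker-depth band used for the gated normalization of
#: experimentally acquired data (marker structure ≈17 mm tall).
DEFAULT_GATE = GateWindow(9.0, 24.0)


def normalize_global(rf: RFChannelData) -> RFChannelData:
    """Divide the tensor by its maximum magnitude (new max |sample| = 1)."""
    peak = np.abs(rf.data).max()
    if peak == 0:
        raise DegenerateInputError("cannot normalize all-zero RF data")
    return rf.with_data(rf.data / peak)


def normalize_gated(rf: RFChannelData, gate: GateWindow) -> RFChannelData:
    """Divide by the maximum magnitude inside the gated depth band.

    Applied after :func:`normalize_global` in the standard workflow;
    samples outside the band may exceed 1 afterwards.
    """
    sl = gate.sample_slice(rf)
    peak = np.abs(rf.data[sl]).max()
    if peak == 0:
        raise DegenerateInputError("gated depth band contains only zeros")
    return rf.with_data(rf.data / peak)


def smooth_trace(trace: np.ndarray, method: str = "moving_average", window: int = 9):
    """Smooth a 1-D trace with a linear kernel of odd length ``window``.

    ``moving_average`` uses a reflective-boundary uniform filter (a
    constant trace stays constant); ``savgol`` uses a quadratic
    Savitzky–Golay filter.  ``window = 1`` is the identity.
    """
    trace = np.asarray(trace, dtype=float)
    if window % 2 == 0 or not 1 <= window <= trace.size:
        raise ValidationError("window must be odd and within the trace length")
    if window == 1:
        return trace.copy()
    if method == "moving_average":
        return uniform_filter1d(trace, size=window, mode="reflect")
    if method == "savgol":
        return savgol_filter(trace, window_length=window, polyorder=min(2, window - 1))
    raise ValidationError(f"unknown smoothing method {method!r}")


def smooth_delay_curve(curve: np.ndarray, window: int = 21, order: int = 2):
    """Savitzky–Golay re-smoothing of a per-scanline delay curve.

    The window is forced to the nearest odd value (a symmetric filter
    needs an odd support); order-``order`` polynomials pass through
    unchanged.  Returns a float curve of the same length.
    """
    curve = np.asarray(curve, dtype=float)
    if window % 2 == 0:
        window += 1
    if curve.size < window:
        raise ValidationError("delay curve shorter than the smoothing window")
    if order >= window:
        raise ValidationError("polynomial order must be below the window size")
    return savgol_filter(curve, window_length=window, polyorder=order, mode="interp")
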