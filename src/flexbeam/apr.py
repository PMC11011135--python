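"""Two-round Aligned Peak Response (APR) delay estimation.

APR reconstructs images from a flexible array whose bent shape is
unknown.  Instead of computing geometric delays from element positions,
it aligns the strong peak echoes returned by a known marker:

* **Round 1 (transmit/reference delays).**  For each scanline, the
  trace received by that scanline's own transmitting element is
  extracted; the sample shift that aligns its gated envelope peak with
  the reference scanline's peak becomes the per-scanline delay
  (``d = Δt · fs`` in samples).
* **Round 2 (receive delays).**  After round 1 is applied, the traces
  of the remaining receive elements within each scanline are aligned
  to the transmitting element's trace the same way.  Element-to-element
  delay increments larger than a threshold (default 5 samples) are
  clamped while walking outward from the transmit element — an outlier
  guard against weak or inconsistent echoes.

The total delay of a (scanline, element) column is the exact sum of its
round-1 and round-2 delays.  All delays are integer samples; positive
delay shifts a trace later in time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .errors import NoPeakError, ValidationError
from .geometry import ArrayGeometry
from .preprocess import (
    GateWindow,
    normalize_gated,
    normalize_global,
    smooth_delay_curve,
)
from .simulate import RFChannelData

__all__ = [
    "APRConfig",
    "DelayCurve",
    "peak_sample",
    "apr_round1",
    "apr_round2",
    "estimate_delays",
    "apply_delays",
    "oracle_delays",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class APRConfig:
    """Tunables of the two-round APR pipeline.

    ``gate`` of ``None`` means the full record (simulation mode, where
    the marker echo is the only signal); supply a :class:`GateWindow`
    (e.g. 9–24 mm) for experimental-style data.  ``reference_scanline``
    may be an explicit index, ``"first"``, ``"middle"`` or
    ``"strongest"`` (the scanline with the largest gated peak
    amplitude; default, since the strongest marker response gives the
    most reliable datum).
    """

    gate: GateWindow | None = None
    reference_scanline: int | str = "strongest"
    threshold: int | None = 5
    envelope_smoothing_window: int = 9
    resmooth_round1: bool = True
    sg_window: int = 21
    sg_order: int = 2
    round2: bool = True
    normalize: bool = True


@dataclass
class DelayCurve:
    """Integer APR delays: per scanline (round 1) and per column (round 2).

    ``total[s, e] = round1[s] + round2[s, e]`` exactly;
    ``round1[reference_scanline] == 0`` and every scanline's own
    transmit-element column has ``round2 == 0``.
    """

    round1: np.ndarray  # (S,) int
    round2: np.ndarray  # (S, E) int
    reference_scanline: int
    gate: GateWindow | None = None
    n_substituted: int = 0

    def __post_init__(self):
        self.round1 = np.asarray(self.round1, dtype=np.int64)
        self.round2 = np.asarray(self.round2, dtype=np.int64)
        if self.round2.ndim != 2 or self.round2.shape[0] != self.round1.size:
            raise ValidationError("round2 must be (n_scanlines, n_elements)")

    @property
    def n_scanlines(self) -> int:
        return self.round1.size

    @property
    def n_elements(self) -> int:
        return self.round2.shape[1]

    @property
    def total(self) -> np.ndarray:
        """(S, E) total delay samples: round1 + round2."""
        return self.round1[:, None] + self.round2


def _envelope(traces: np.ndarray, smooth_window: int) -> np.ndarray:
    """Smoothed analytic-signal magnitude along axis 0."""
    env = np.abs(hilbert(traces, axis=0))
    if smooth_window > 1:
        env = uniform_filter1d(env, size=smooth_window, axis=0, mode="reflect")
    return env


def peak_sample(
    trace: np.ndarray,
    gate: slice | None = None,
    smooth_window: int = 9,
) -> int:
    """Sample index of the gated peak of the smoothed envelope.

    Ties break toward the earliest sample.  Raises :class:`NoPeakError`
    when the gated segment is identically zero.
    """
    trace = np.asarray(trace, dtype=float)
    env = _envelope(trace[:, None], smooth_window)[:, 0]
    sl = gate if gate is not None else slice(0, trace.size)
    seg = env[sl]
    if seg.size == 0:
        raise ValidationError("empty gate")
    if seg.max() <= 0:
        raise NoPeakError("gated segment contains no signal")
    return int(sl.start or 0) + int(np.argmax(seg))


def _gated_peaks(env: np.ndarray, sl: slice):
    """Per-column peak index and amplitude of a gated envelope block.

    ``env`` is (n_samples, n_cols); columns whose gated segment is all
    zero get index −1.
    """
    seg = env[sl]
    idx = np.argmax(seg, axis=0) + (sl.start or 0)
    amp = seg.max(axis=0)
    idx = np.where(amp > 0, idx, -1)
    return idx, amp


def _fill_invalid(values: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace invalid entries by the nearest valid neighbor's value."""
    n_bad = int(np.count_nonzero(~valid))
    if n_bad == 0:
        return values, 0
    pos = np.arange(values.size)
    good = pos[valid]
    filled = values.copy()
    nearest = good[np.argmin(np.abs(pos[~valid][:, None] - good[None, :]), axis=1)]
    filled[~valid] = values[nearest]
    return filled, n_bad


def _resolve_reference(rf: RFChannelData, reference, gate_slice, smooth_window) -> int:
    if isinstance(reference, (int, np.integer)):
        if not 0 <= reference < rf.n_scanlines:
            raise ValidationError("reference scanline out of range")
        return int(reference)
    if reference == "first":
        return 0
    if reference == "middle":
        return rf.n_scanlines // 2
    if reference == "strongest":
        own = rf.data[:, rf.tx_element_of_scanline, np.arange(rf.n_scanlines)]
        env = _envelope(own, smooth_window)
        _, amp = _gated_peaks(env, gate_slice)
        return int(np.argmax(amp))
    raise ValidationError(f"unknown reference selector {reference!r}")


def apr_round1(
    rf: RFChannelData,
    gate: GateWindow | None = None,
    reference_scanline: int | str = 0,
    smooth_window: int = 9,
):
    """First-round (per-scanline) APR delays.

    Returns ``(round1, reference_index, n_substituted)`` where
    ``round1[s] = p_ref − p_s`` is the shift aligning scanline ``s``'s
    own-transmit-element peak to the reference scanline's peak.
    Scanlines without a detectable peak inherit the nearest valid
    neighbor's delay (a no-peak on the reference itself is fatal).
    """
    sl = gate.sample_slice(rf) if gate is not None else slice(0, rf.n_samples)
    own = rf.data[:, rf.tx_element_of_scanline, np.arange(rf.n_scanlines)]
    env = _envelope(own, smooth_window)
    p, amp = _gated_peaks(env, sl)
    ref = _resolve_reference(rf, reference_scanline, sl, smooth_window)
    if p[ref] < 0:
        raise NoPeakError(f"reference scanline {ref} has no gated peak")
    p_filled, n_bad = _fill_invalid(p, p >= 0)
    if n_bad:
        log.warning("round 1: %d scanline(s) had no gated peak; copied neighbors", n_bad)
    round1 = p_filled[ref] - p_filled
    return round1.astype(np.int64), ref, n_bad


def apr_round2(
    rf: RFChannelData,
    gate: GateWindow | None = None,
    threshold: int | None = 5,
    smooth_window: int = 9,
):
    """Second-round (per-element) APR delays on round-1-aligned data.

    Within each scanline, every element's gated peak is aligned to the
    transmitting element's peak.  Walking outward from the transmit
    element, element-to-element delay increments with magnitude above
    ``threshold`` are clamped to the threshold-bounded value relative
    to the previous element; ``threshold=None`` disables clamping.
    Columns without a peak copy the inner neighbor's delay.

    Returns ``(round2, n_substituted)``.
    """
    if threshold is not None and threshold < 0:
        raise ValidationError("threshold must be >= 0")
    sl = gate.sample_slice(rf) if gate is not None else slice(0, rf.n_samples)
    S, E = rf.n_scanlines, rf.n_elements
    round2 = np.zeros((S, E), dtype=np.int64)
    n_bad_total = 0
    for s in range(S):
        e0 = rf.tx_element_of_scanline[s]
        env = _envelope(rf.data[:, :, s], smooth_window)
        p, amp = _gated_peaks(env, sl)
        if p[e0] < 0:
            log.warning("round 2: scanline %d transmit trace has no peak", s)
            n_bad_total += 1
            continue
        raw = p[e0] - p  # shift aligning each element's peak to the tx trace
        d = np.zeros(E, dtype=np.int64)
        for direction in (1, -1):
            r = e0 + direction
            while 0 <= r < E:
                prev = d[r - direction]
                if p[r] < 0:
                    d[r] = prev
                    n_bad_total += 1
                else:
                    inc = int(raw[r]) - prev
                    if threshold is not None and abs(inc) > threshold:
                        inc = threshold if inc > 0 else -threshold
                    d[r] = prev + inc
                r += direction
        round2[s] = d
    if n_bad_total:
        log.warning("round 2: %d column(s) substituted from neighbors", n_bad_total)
    return round2, n_bad_total


def apply_delays(rf: RFChannelData, delays) -> RFChannelData:
    """Shift every column trace by its total integer delay.

    Positive delay moves the trace later in time; vacated samples are
    zero-padded.  ``delays`` may be a :class:`DelayCurve` or an
    (n_scanlines, n_elements) integer array.
    """
    total = delays.total if isinstance(delays, DelayCurve) else np.asarray(delays)
    total = total.astype(np.int64)
    if total.shape != (rf.n_scanlines, rf.n_elements):
        raise ValidationError("delay dimensions do not match the RF data")
    N = rf.n_samples
    if np.any(np.abs(total) >= N):
        raise ValidationError("|delay| must be smaller than the record length")
    out = np.zeros_like(rf.data, dtype=float)
    for s in range(rf.n_scanlines):
        for d in np.unique(total[s]):
            cols = np.nonzero(total[s] == d)[0]
            if d > 0:
                out[d:, cols, s] = rf.data[: N - d, cols, s]
            elif d < 0:
                out[: N + d, cols, s] = rf.data[-d:, cols, s]
            else:
                out[:, cols, s] = rf.data[:, cols, s]
    return rf.with_data(out)


def estimate_delays(rf: RFChannelData, config: APRConfig = APRConfig()) -> DelayCurve:
    """Full two-round APR estimation on an RF channel dataset.

    Workflow: global (then gated, when a gate is configured)
    normalization → round 1 on the own-transmit-element traces →
    optional Savitzky–Golay re-smoothing of the round-1 curve (rounded
    back to integer samples and re-anchored so the reference stays at
    0) → round 1 applied → round 2 with outlier clamping.
    """
    work = rf
    if config.normalize:
        work = normalize_global(work)
        if config.gate is not None:
            work = normalize_gated(work, config.gate)

    round1, ref, n_bad1 = apr_round1(
        work,
        gate=config.gate,
        reference_scanline=config.reference_scanline,
        smooth_window=config.envelope_smoothing_window,
    )

    if config.resmooth_round1 and round1.size >= config.sg_window:
        smoothed = smooth_delay_curve(round1, config.sg_window, config.sg_order)
        round1 = np.rint(smoothed).astype(np.int64)
        round1 = round1 - round1[ref]  # keep the reference anchored at 0

    if config.round2:
        aligned = apply_delays(
            work, np.broadcast_to(round1[:, None], (rf.n_scanlines, rf.n_elements))
        )
        round2, n_bad2 = apr_round2(
            aligned,
            gate=config.gate,
            threshold=config.threshold,
            smooth_window=config.envelope_smoothing_window,
        )
    else:
        round2, n_bad2 = np.zeros((rf.n_scanlines, rf.n_elements), dtype=np.int64), 0

    return DelayCurve(
        round1=round1,
        round2=round2,
        reference_scanline=ref,
        gate=config.gate,
        n_substituted=n_bad1 + n_bad2,
    )


def oracle_delays(
    geometry: ArrayGeometry,
    marker_xz,
    *,
    fs: float,
    sound_speed: float,
    t0: float = 0.0,
    tx_map: np.ndarray | None = None,
    reference_scanline: int | str = "strongest",
) -> DelayCurve:
    """Ground-truth geometric delays for a single known marker.

    Computed directly from element positions: the peak of column
    (s, e) sits at ``t[s, e] = tof(tx_s, e, marker)``, and the delays
    are the shifts aligning every column to the reference scanline's
    own-transmit-element arrival — exactly what a perfect APR would
    estimate.  ``"strongest"`` resolves to the scanline whose transmit
    element is closest to the marker.
    """
    marker = np.asarray(marker_xz, dtype=float)
    E = geometry.n_elements
    tx_map = np.arange(E) if tx_map is None else np.asarray(tx_map, dtype=int)
    S = tx_map.size
    c_mm = sound_speed * 1e3
    d = np.hypot(marker[0] - geometry.element_x, marker[1] - geometry.element_z)  # (E,)
    t = ((d[tx_map][:, None] + d[None, :]) / c_mm - t0) * fs  # (S, E) samples
    own = t[np.arange(S), tx_map]
    if reference_scanline == "strongest":
        ref = int(np.argmin(d[tx_map]))
    elif reference_scanline == "middle":
        ref = S // 2
    elif reference_scanline == "first":
        ref = 0
    else:
        ref = int(reference_scanline)
    round1 = np.rint(own[ref] - own).astype(np.int64)
    round2 = np.rint(own[:, None] - t).astype(np.int64)
    return DelayCurve(round1=round1, round2=round2, reference_scanline=ref)
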