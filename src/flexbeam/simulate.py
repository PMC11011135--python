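"""Synthetic RF channel data from phantoms, and artificial curvature.

This is a desk-scale time-of-flight scatterer simulator: every
scatterer contributes a Gaussian-modulated pulse replica on every
receive trace, centered at the exact two-way time of flight, with
1/(r_tx·r_rx) spherical-spreading amplitude.  It deliberately omits
spatial-impulse-response physics (element surface integration,
elevation aperture, nonlinear propagation); the delay-estimation
method under study is driven by arrival *times*, which this model
reproduces exactly.

The module also provides :func:`curve_rf`, which re-delays RF data
acquired with one array shape so that it looks as if it had been
acquired with another shape — the artificial-curvature construction
used to obtain curved-probe data with a known ground-truth geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import gausspulse

from .errors import ValidationError
from .geometry import ArrayGeometry

__all__ = [
    "Pulse",
    "Phantom",
    "RFChannelData",
    "make_marker_phantom",
    "point_targets",
    "simulate_rf",
    "curve_rf",
    "suggest_n_samples",
]

#: mm below which the 1/r amplitude weighting is clamped (near-field guard).
_MIN_RANGE_MM = 0.25

DEFAULT_SOUND_SPEED = 1540.0  # m/s


@dataclass(frozen=True)
class Pulse:
    """Transmit pulse model: Gaussian-modulated sinusoid.

    Defaults: 5 MHz center frequency, fractional bandwidth 0.6
    (at −6 dB), sampled at 40 MHz.
    """

    center_frequency: float = 5e6
    fractional_bandwidth: float = 0.6
    fs: float = 40e6

    def __post_init__(self):
        if not 0 < self.fractional_bandwidth < 2:
            raise ValidationError("fractional_bandwidth must be in (0, 2)")
        if self.fs <= 2 * self.center_frequency:
            raise ValidationError("fs must exceed twice the center frequency")

    def waveform(self, t):
        """Pulse amplitude at times ``t`` (s); envelope peak at t = 0."""
        return gausspulse(
            np.asarray(t, dtype=float),
            fc=self.center_frequency,
            bw=self.fractional_bandwidth,
        )

    def half_duration(self, eps: float = 1e-8) -> float:
        """Half-width (s) beyond which the envelope is below ``eps``."""
        # gausspulse envelope exp(-a t^2) with the -6 dB bandwidth reference
        ref = 10 ** (-6 / 20.0)
        a = -((np.pi * self.center_frequency * self.fractional_bandwidth) ** 2) / (
            4.0 * np.log(ref)
        )
        return float(np.sqrt(-np.log(eps) / a))


@dataclass(frozen=True)
class Phantom:
    """Scatterer cloud: positions (mm), reflectivities, optional labels."""

    x: np.ndarray
    z: np.ndarray
    amplitude: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        x = np.atleast_1d(np.asarray(self.x, dtype=float))
        z = np.atleast_1d(np.asarray(self.z, dtype=float))
        a = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "amplitude", a)
        if not (x.shape == z.shape == a.shape):
            raise ValidationError("x, z, amplitude must have matching shapes")
        if x.size and np.any(z <= 0):
            raise ValidationError("scatterers must lie below the aperture (z > 0)")
        if not np.all(np.isfinite(a)):
            raise ValidationError("amplitudes must be finite")

    @property
    def n_scatterers(self) -> int:
        return self.x.size

    def scaled(self, factor: float) -> "Phantom":
        return replace(self, amplitude=self.amplitude * factor)


def point_targets(coords_mm, amplitude=1.0, label="marker") -> Phantom:
    """Phantom of discrete point targets at (x, z) mm coordinates."""
    pts = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    amps = np.broadcast_to(np.asarray(amplitude, dtype=float), pts.shape[0]).copy()
    return Phantom(pts[:, 0], pts[:, 1], amps, labels=(label,) * pts.shape[0])


def make_marker_phantom(
    kind: str,
    *,
    n_scatterers: int = 10_000,
    lateral_span=(-40.0, 40.0),
    depth_span=(25.0, 55.0),
    disc_center=(0.0, 40.0),
    disc_radius: float = 5.0,
    disc_contrast: float = 0.0,
    seed: int | None = None,
) -> Phantom:
    """Construct one of the study phantoms.

    ``center_point``: one target at (0, 30) mm.
    ``two_points``: targets at (−30, 30) and (30, 30) mm.
    ``right_point``: one target at (30, 30) mm.
    ``scatter_cloud``: ``n_scatterers`` seeded uniform scatterers with
    Gaussian reflectivity and an embedded circular region whose
    amplitude is scaled by ``disc_contrast`` (0 = anechoic).
    """
    if kind == "center_point":
        return point_targets([(0.0, 30.0)])
    if kind == "two_points":
        return point_targets([(-30.0, 30.0), (30.0, 30.0)])
    if kind == "right_point":
        return point_targets([(30.0, 30.0)])
    if kind == "scatter_cloud":
        if seed is None:
            raise ValidationError("scatter_cloud requires a seed")
        rng = np.random.default_rng(seed)
        x = rng.uniform(*lateral_span, size=n_scatterers)
        z = rng.uniform(*depth_span, size=n_scatterers)
        amp = rng.standard_normal(n_scatterers)
        inside = (x - disc_center[0]) ** 2 + (z - disc_center[1]) ** 2 <= disc_radius**2
        amp[inside] *= disc_contrast
        return Phantom(x, z, amp, labels=("background",) * n_scatterers)
    raise ValidationError(f"unknown phantom kind {kind!r}")


@dataclass
class RFChannelData:
    """RF channel tensor [n_samples × n_elements × n_scanlines] + metadata.

    ``t0`` is the time of sample 0 relative to transmit;
    ``tx_element_of_scanline`` maps each scanline to its single
    transmitting element (identity map by default).  ``geometry`` is
    optional: shape-unknown data simply omit it.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    sound_speed: float = DEFAULT_SOUND_SPEED
    tx_element_of_scanline: np.ndarray | None = None
    geometry: ArrayGeometry | None = None
    #: lateral position (mm) of each scanline's beam axis.  This is an
    #: acquisition property: artificially curving the data does not move
    #: the lines the scanlines were recorded along.  Derived from the
    #: geometry when omitted.
    scanline_x: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError("data must be [n_samples, n_elements, n_scanlines]")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("all RF samples must be finite")
        if self.tx_element_of_scanline is None:
            if self.n_elements != self.n_scanlines:
                raise ValidationError(
                    "tx_element_of_scanline required when n_elements != n_scanlines"
                )
            self.tx_element_of_scanline = np.arange(self.n_scanlines)
        self.tx_element_of_scanline = np.asarray(self.tx_element_of_scanline, dtype=int)
        if self.tx_element_of_scanline.shape != (self.n_scanlines,):
            raise ValidationError("tx map must have one entry per scanline")
        if np.any(self.tx_element_of_scanline < 0) or np.any(
            self.tx_element_of_scanline >= self.n_elements
        ):
            raise ValidationError("tx map entries out of element range")
        if self.geometry is not None and self.geometry.n_elements != self.n_elements:
            raise ValidationError("geometry element count mismatch")
        if self.scanline_x is None and self.geometry is not None:
            self.scanline_x = self.geometry.element_x[self.tx_element_of_scanline].copy()
        if self.scanline_x is not None:
            self.scanline_x = np.asarray(self.scanline_x, dtype=float)
            if self.scanline_x.shape != (self.n_scanlines,):
                raise ValidationError("scanline_x must have one entry per scanline")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_elements(self) -> int:
        return self.data.shape[1]

    @property
    def n_scanlines(self) -> int:
        return self.data.shape[2]

    @property
    def sample_times(self) -> np.ndarray:
        """Receive time of each sample (s): t = t0 + n/fs."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    @property
    def depth_axis_mm(self) -> np.ndarray:
        """Pulse-echo depth of each sample: z = c·t/2, in mm."""
        return self.sound_speed * 1e3 * self.sample_times / 2.0

    def with_data(self, data: np.ndarray, geometry="__keep__") -> "RFChannelData":
        """Copy of this container with new samples (metadata preserved).

        Pass ``geometry=None`` to drop the geometry or a new
        :class:`ArrayGeometry` to replace it.
        """
        geom = self.geometry if isinstance(geometry, str) else geometry
        return RFChannelData(
            data=data,
            fs=self.fs,
            t0=self.t0,
            sound_speed=self.sound_speed,
            tx_element_of_scanline=self.tx_element_of_scanline.copy(),
            geometry=geom,
            scanline_x=None if self.scanline_x is None else self.scanline_x.copy(),
        )


def _distances(geometry: ArrayGeometry, phantom: Phantom) -> np.ndarray:
    """(n_scatterers, n_elements) element↔scatterer distances in mm."""
    dx = phantom.x[:, None] - geometry.element_x[None, :]
    dz = phantom.z[:, None] - geometry.element_z[None, :]
    return np.hypot(dx, dz)


def suggest_n_samples(
    phantom: Phantom,
    geometry: ArrayGeometry,
    pulse: Pulse,
    sound_speed: float = DEFAULT_SOUND_SPEED,
    t0: float = 0.0,
) -> int:
    """Record length covering every two-way echo plus the pulse tail."""
    if phantom.n_scatterers == 0:
        return 1024
    d = _distances(geometry, phantom)  # mm
    c_mm = sound_speed * 1e3
    t_max = 2.0 * d.max() / c_mm + pulse.half_duration()
    return int(np.ceil((t_max - t0) * pulse.fs)) + 8


def simulate_rf(
    phantom: Phantom,
    geometry: ArrayGeometry,
    pulse: Pulse,
    *,
    tx_map: np.ndarray | None = None,
    n_samples: int | None = None,
    noise_level: float = 0.0,
    seed: int | None = None,
    t0: float = 0.0,
    sound_speed: float = DEFAULT_SOUND_SPEED,
    directivity: bool = False,
) -> RFChannelData:
    """Simulate single-element-transmit RF channel data.

    Every scanline transmits on one element (``tx_map``, identity by
    default) and receives on all elements.  Each scatterer adds a pulse
    replica of amplitude ``a / (r_tx · r_rx)`` centered at the exact
    two-way ToF sample.  Optional white Gaussian noise of standard
    deviation ``noise_level × max|clean data|`` is added (seeded).

    Raises
    ------
    ValidationError
        If ``n_samples`` is too small to contain any echo, or if
        ``noise_level > 0`` without a seed.
    """
    if noise_level < 0:
        raise ValidationError("noise_level must be >= 0")
    if noise_level > 0 and seed is None:
        raise ValidationError("seed required when noise_level > 0")
    E = geometry.n_elements
    tx_map = np.arange(E) if tx_map is None else np.asarray(tx_map, dtype=int)
    S = tx_map.size
    if n_samples is None:
        n_samples = suggest_n_samples(phantom, geometry, pulse, sound_speed, t0)

    c_mm = sound_speed * 1e3
    data = np.zeros((n_samples, E, S), dtype=float)

    if phantom.n_scatterers:
        d_all = _distances(geometry, phantom)  # (K, E) mm
        first_arrival = (2.0 * d_all.min(axis=1) / c_mm - t0) * pulse.fs
        if np.all(first_arrival >= n_samples):
            raise ValidationError(
                "n_samples too small: no echo falls inside the record"
            )
        half_w = int(np.ceil(pulse.half_duration() * pulse.fs))
        offs = np.arange(-half_w, half_w + 1)
        r_eff = np.maximum(d_all, _MIN_RANGE_MM)
        if directivity:
            normals = geometry.normals  # (E, 2)
            vx = phantom.x[:, None] - geometry.element_x[None, :]
            vz = phantom.z[:, None] - geometry.element_z[None, :]
            cosang = (vx * normals[None, :, 0] + vz * normals[None, :, 1]) / np.maximum(
                d_all, _MIN_RANGE_MM
            )
            dir_gain = np.clip(cosang, 0.0, None)
        el_idx = np.broadcast_to(np.arange(E)[None, :, None], (phantom.n_scatterers, E, offs.size))
        for s in range(S):
            e = tx_map[s]
            tof_se = (d_all[:, e][:, None] + d_all) / c_mm  # (K, E) seconds
            amp = phantom.amplitude[:, None] / (r_eff[:, e][:, None] * r_eff)
            if directivity:
                amp = amp * dir_gain[:, e][:, None] * dir_gain
            center = (tof_se - t0) * pulse.fs  # float sample index
            base = np.rint(center).astype(np.int64)
            idx = base[:, :, None] + offs[None, None, :]
            t_rel = (idx - center[:, :, None]) / pulse.fs
            vals = amp[:, :, None] * pulse.waveform(t_rel)
            valid = (idx >= 0) & (idx < n_samples)
            np.add.at(data[:, :, s], (idx[valid], el_idx[valid]), vals[valid])

    if noise_level > 0:
        scale = np.abs(data).max()
        if scale == 0:
            scale = 1.0
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_level * scale, size=data.shape)

    return RFChannelData(
        data=data,
        fs=pulse.fs,
        t0=t0,
        sound_speed=sound_speed,
        tx_element_of_scanline=tx_map,
        geometry=geometry,
    )


def _interp_columns(mat: np.ndarray, coords: np.ndarray, mode: str) -> np.ndarray:
    """Gather ``mat[coords[n, r], r]`` with linear or nearest interpolation.

    ``mat`` is (n_samples, n_elements); ``coords`` is float sample
    positions of shape (n_out, n_elements).  Out-of-range positions
    yield 0.
    """
    n = mat.shape[0]
    r_idx = np.broadcast_to(np.arange(mat.shape[1])[None, :], coords.shape)
    if mode == "nearest":
        i = np.rint(coords).astype(np.int64)
        inside = (i >= 0) & (i < n)
        out = np.zeros_like(coords)
        out[inside] = mat[i[inside], r_idx[inside]]
        return out
    if mode != "linear":
        raise ValidationError(f"unknown interpolation mode {mode!r}")
    i0 = np.floor(coords).astype(np.int64)
    frac = coords - i0
    inside = (i0 >= 0) & (i0 < n - 1)
    out = np.zeros_like(coords)
    out[inside] = (1.0 - frac[inside]) * mat[i0[inside], r_idx[inside]] + frac[
        inside
    ] * mat[i0[inside] + 1, r_idx[inside]]
    # exact hit on the last sample
    last = coords == n - 1
    out[last] = mat[n - 1, r_idx[last]]
    return out


#: oversampling factor of the band-limited fractional-delay resampler
_BL_FACTOR = 8


def _gather_columns(mat: np.ndarray, coords: np.ndarray, mode: str) -> np.ndarray:
    """Fractionally resample the columns of ``mat`` at float positions.

    ``bandlimited`` (default elsewhere) FFT-oversamples each column by
    ``_BL_FACTOR`` before linear interpolation, keeping sub-sample
    errors of band-limited RF signals at the 0.1% level; ``linear`` and
    ``nearest`` operate on the raw grid.
    """
    if mode == "bandlimited":
        from scipy.signal import resample

        fine = resample(mat, mat.shape[0] * _BL_FACTOR, axis=0)
        return _interp_columns(fine, coords * _BL_FACTOR, "linear")
    return _interp_columns(mat, coords, mode)


def curve_rf(
    rf: RFChannelData,
    target_geometry: ArrayGeometry,
    mode: str = "bandlimited",
) -> RFChannelData:
    """Artificially curve RF data to mimic acquisition with another shape.

    For each scanline the focal points are taken one per depth sample
    along the scanline's recorded beam axis (``scanline_x``, the
    vertical line through the transmit element of the acquisition
    geometry).  For every receive element the
    pairs (two-way ToF with the source shape, two-way ToF with the
    target shape) tabulated on that focal grid define a monotone time
    warp; each channel trace is resampled through it, so an echo that
    arrives at ``tof_source(P)`` in the input appears at
    ``tof_target(P)`` in the output for every on-axis focal point P.

    The returned container carries ``target_geometry``.
    """
    if rf.geometry is None:
        raise ValidationError("curve_rf requires the source geometry on the data")
    src = rf.geometry
    if target_geometry.n_elements != src.n_elements:
        raise ValidationError("element counts of source and target differ")

    N, E, S = rf.data.shape
    c_mm = rf.sound_speed * 1e3
    z_grid = np.maximum(rf.depth_axis_mm, 1e-9)  # mm, one focal point per sample
    t_out = rf.sample_times
    out = np.zeros_like(rf.data, dtype=float)

    axis_x = (
        rf.scanline_x
        if rf.scanline_x is not None
        else src.element_x[rf.tx_element_of_scanline]
    )
    for s in range(S):
        e = rf.tx_element_of_scanline[s]
        ax = axis_x[s]
        # legs from every element to every on-axis focal point, (N, E) mm
        dz_src = z_grid[:, None] - src.element_z[None, :]
        d_src = np.hypot(ax - src.element_x[None, :], dz_src)
        d_tgt = np.hypot(
            ax - target_geometry.element_x[None, :],
            z_grid[:, None] - target_geometry.element_z[None, :],
        )
        t_src = (d_src[:, e][:, None] + d_src) / c_mm  # (N, E) s
        t_tgt = (d_tgt[:, e][:, None] + d_tgt) / c_mm
        coords = np.empty((N, E))
        for r in range(E):
            # Invert the target-time axis: output time -> source time.
            # For a curved target the two-way ToF along the axis is not
            # monotone above the (raised) element height; restrict the
            # inversion to the deeper, monotone branch.
            k0 = int(np.argmin(t_tgt[:, r]))
            src_time = np.interp(t_out, t_tgt[k0:, r], t_src[k0:, r])
            coords[:, r] = (src_time - rf.t0) * rf.fs
        out[:, :, s] = _gather_columns(rf.data[:, :, s], coords, mode)

    return rf.with_data(out, geometry=target_geometry)
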