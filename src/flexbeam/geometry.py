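"""Flexible-array element geometries and two-way time of flight.

Coordinate convention: ``x`` is lateral (mm, increasing with element
index), ``z`` is axial depth (mm, positive into the medium).  The origin
sits at the aperture's lateral center on the skin line, so a flat array
lies on ``z = 0`` and a convex bend pushes the edge elements to ``z > 0``
while the apex element stays on the skin line.

All positions are in millimetres; sound speed is in m/s; times are in
seconds.  These units are used consistently by every module downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ValidationError

__all__ = ["ArrayGeometry", "make_geometry", "tof"]

#: Default probe: 128 elements at 1 mm pitch (≈128 mm footprint).
DEFAULT_N_ELEMENTS = 128
DEFAULT_PITCH_MM = 1.0


@dataclass(frozen=True)
class ArrayGeometry:
    """Per-element 2-D positions of a flexible aperture.

    Parameters
    ----------
    element_x, element_z
        Lateral / axial element positions in mm (depth-positive).
    pitch
        Inter-element spacing *along the curve* in mm.
    shape_label
        One of ``flat``, ``arc``, ``polyline``.
    radius
        Curvature radius in mm (``arc`` only, convex toward the medium).
    """

    element_x: np.ndarray
    element_z: np.ndarray
    pitch: float
    shape_label: str
    radius: float | None = None

    def __post_init__(self):
        x = np.asarray(self.element_x, dtype=float)
        z = np.asarray(self.element_z, dtype=float)
        object.__setattr__(self, "element_x", x)
        object.__setattr__(self, "element_z", z)
        if x.ndim != 1 or z.shape != x.shape:
            raise ValidationError("element_x/element_z must be matching 1-D arrays")
        if x.size < 2:
            raise ValidationError("an array needs at least 2 elements")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
            raise ValidationError("element positions must be finite")
        if not np.all(np.diff(x) > 0):
            raise ValidationError("element_x must be strictly increasing")
        if self.pitch <= 0:
            raise ValidationError("pitch must be positive")

    @property
    def n_elements(self) -> int:
        return self.element_x.size

    @property
    def positions(self) -> np.ndarray:
        """(n_elements, 2) array of (x, z) positions in mm."""
        return np.stack([self.element_x, self.element_z], axis=1)

    @property
    def normals(self) -> np.ndarray:
        """(n_elements, 2) unit normals pointing into the medium (+z)."""
        if self.shape_label == "flat":
            n = np.zeros((self.n_elements, 2))
            n[:, 1] = 1.0
            return n
        if self.shape_label == "arc":
            # circle center at (0, R); into-medium normal points toward it
            center = np.array([0.0, self.radius])
            v = center[None, :] - self.positions
            return v / np.linalg.norm(v, axis=1, keepdims=True)
        # polyline: normal from local tangent, oriented toward +z
        tx = np.gradient(self.element_x)
        tz = np.gradient(self.element_z)
        n = np.stack([-tz, tx], axis=1)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        n[n[:, 1] < 0] *= -1.0
        return n

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "shape": self.shape_label,
            "n_elements": int(self.n_elements),
            "pitch_mm": float(self.pitch),
            "element_x_mm": self.element_x.tolist(),
            "element_z_mm": self.element_z.tolist(),
        }
        if self.radius is not None:
            doc["radius_mm"] = float(self.radius)
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "ArrayGeometry":
        doc = json.loads(text)
        return cls(
            element_x=np.asarray(doc["element_x_mm"], dtype=float),
            element_z=np.asarray(doc["element_z_mm"], dtype=float),
            pitch=float(doc["pitch_mm"]),
            shape_label=doc["shape"],
            radius=doc.get("radius_mm"),
        )


def make_geometry(
    shape_label: str,
    n_elements: int = DEFAULT_N_ELEMENTS,
    pitch: float = DEFAULT_PITCH_MM,
    radius: float | None = None,
    points: np.ndarray | None = None,
) -> ArrayGeometry:
    """Construct a flat, circular-arc, or polyline array geometry.

    The result is centered so the mean lateral position is 0.  Arc
    elements are equally spaced *in arc length* (a bent physical array
    preserves inter-element arc distance), convex toward the medium:
    the apex element sits at ``z = 0`` and the edges at ``z > 0``.

    Parameters
    ----------
    shape_label
        ``"flat"``, ``"arc"`` (requires ``radius`` in mm) or
        ``"polyline"`` (requires explicit ``points`` of shape (n, 2)).
    """
    if n_elements < 2:
        raise ValidationError("n_elements must be >= 2")
    if pitch <= 0:
        raise ValidationError("pitch must be > 0")

    if shape_label == "flat":
        x = (np.arange(n_elements) - (n_elements - 1) / 2.0) * pitch
        z = np.zeros(n_elements)
        return ArrayGeometry(x, z, pitch, "flat")

    if shape_label == "arc":
        if radius is None:
            raise ValidationError("arc geometry requires a radius (mm)")
        half_aperture = (n_elements - 1) * pitch / 2.0
        if radius <= half_aperture:
            raise GeometryError(
                f"radius {radius} mm too small for a "
                f"{2 * half_aperture:.1f} mm aperture"
            )
        s = (np.arange(n_elements) - (n_elements - 1) / 2.0) * pitch
        theta = s / radius
        x = radius * np.sin(theta)
        # 2R sin^2(theta/2) == R(1 - cos theta), stable for tiny theta
        z = 2.0 * radius * np.sin(theta / 2.0) ** 2
        return ArrayGeometry(x, z, pitch, "arc", radius=radius)

    if shape_label == "polyline":
        if points is None:
            raise ValidationError("polyline geometry requires explicit points")
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] != n_elements:
            raise ValidationError("points must have shape (n_elements, 2)")
        x = pts[:, 0] - pts[:, 0].mean()
        z = pts[:, 1]
        seg = np.hypot(np.diff(x), np.diff(z))
        return ArrayGeometry(x, z, float(seg.mean()), "polyline")

    raise ValidationError(f"unknown shape_label {shape_label!r}")


def tof(
    geometry: ArrayGeometry,
    tx_index: int,
    rx_index: int,
    point_xz,
    sound_speed: float,
):
    """Two-way time of flight tx element → point → rx element, in seconds.

    ``point_xz`` may be a single (x, z) pair in mm or an array with
    trailing dimension 2; the result is broadcast accordingly.  A point
    coincident with one element simply contributes a zero-length leg.
    """
    if sound_speed <= 0:
        raise ValidationError("sound_speed must be > 0")
    n = geometry.n_elements
    if not (0 <= tx_index < n and 0 <= rx_index < n):
        raise ValidationError("element index out of range")
    p = np.asarray(point_xz, dtype=float)
    ptx = geometry.positions[tx_index]
    prx = geometry.positions[rx_index]
    d_tx = np.linalg.norm(p - ptx, axis=-1)
    d_rx = np.linalg.norm(p - prx, axis=-1)
    c_mm = sound_speed * 1e3  # mm/s
    return (d_tx + d_rx) / c_mm
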