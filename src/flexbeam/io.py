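"""Container I/O: RF channel data, delay curves, images.

The primary RF container is HDF5 with dataset ``rf`` (little-endian
float32, [n_samples, n_elements, n_scanlines]) and attributes
``fs_hz``, ``t0_s``, ``c_mps``, ``tx_map`` and ``geometry_json``.  A
two-file fallback (raw little-endian float32 + JSON sidecar) covers
toolchains without HDF5 support.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from .apr import DelayCurve
from .beamform import BModeImage
from .errors import FormatError
from .geometry import ArrayGeometry
from .preprocess import GateWindow
from .simulate import RFChannelData

__all__ = [
    "read_rf",
    "write_rf",
    "read_delays",
    "write_delays",
    "save_png",
    "write_image",
    "read_image",
]

_REQUIRED_ATTRS = ("fs_hz", "t0_s", "c_mps")


def _is_raw(path: Path) -> bool:
    return path.suffix in {".raw", ".f32"}


def write_rf(path, rf: RFChannelData) -> Path:
    """Write RF channel data; format chosen by extension.

    ``.h5``/``.hdf5`` → HDF5 container; ``.raw``/``.f32`` → raw
    float32 + ``<path>.json`` sidecar.
    """
    path = Path(path)
    geom_json = rf.geometry.to_json() if rf.geometry is not None else ""
    if _is_raw(path):
        rf.data.astype("<f4").tofile(path)
        sidecar = {
            "shape": list(rf.data.shape),
            "dtype": "<f4",
            "fs_hz": rf.fs,
            "t0_s": rf.t0,
            "c_mps": rf.sound_speed,
            "tx_map": rf.tx_element_of_scanline.tolist(),
            "geometry_json": geom_json,
            "scanline_x_mm": None
            if rf.scanline_x is None
            else rf.scanline_x.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
        return path
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=rf.data.astype("<f4"))
        f.attrs["fs_hz"] = rf.fs
        f.attrs["t0_s"] = rf.t0
        f.attrs["c_mps"] = rf.sound_speed
        f.attrs["tx_map"] = rf.tx_element_of_scanline
        f.attrs["geometry_json"] = geom_json
        if rf.scanline_x is not None:
            f.attrs["scanline_x_mm"] = rf.scanline_x
    return path


def read_rf(path) -> RFChannelData:
    """Read RF channel data written by :func:`write_rf`."""
    path = Path(path)
    if _is_raw(path):
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise FormatError(f"missing sidecar {sidecar_path.name}")
        meta = json.loads(sidecar_path.read_text())
        missing = [k for k in _REQUIRED_ATTRS if k not in meta]
        if missing:
            raise FormatError(f"sidecar missing required keys: {', '.join(missing)}")
        data = np.fromfile(path, dtype=meta.get("dtype", "<f4")).reshape(meta["shape"])
        geom_json = meta.get("geometry_json", "")
        return RFChannelData(
            data=data.astype(float),
            fs=float(meta["fs_hz"]),
            t0=float(meta["t0_s"]),
            sound_speed=float(meta["c_mps"]),
            tx_element_of_scanline=np.asarray(meta["tx_map"], dtype=int)
            if "tx_map" in meta
            else None,
            geometry=ArrayGeometry.from_json(geom_json) if geom_json else None,
            scanline_x=np.asarray(meta["scanline_x_mm"], dtype=float)
            if meta.get("scanline_x_mm") is not None
            else None,
        )
    with h5py.File(path, "r") as f:
        if "rf" not in f:
            raise FormatError("missing dataset 'rf'")
        missing = [k for k in _REQUIRED_ATTRS if k not in f.attrs]
        if missing:
            raise FormatError(f"missing required attributes: {', '.join(missing)}")
        data = f["rf"][()]
        geom_json = f.attrs.get("geometry_json", "")
        tx = f.attrs["tx_map"] if "tx_map" in f.attrs else None
        return RFChannelData(
            data=data.astype(float),
            fs=float(f.attrs["fs_hz"]),
            t0=float(f.attrs["t0_s"]),
            sound_speed=float(f.attrs["c_mps"]),
            tx_element_of_scanline=np.asarray(tx, dtype=int) if tx is not None else None,
            geometry=ArrayGeometry.from_json(geom_json) if geom_json else None,
            scanline_x=np.asarray(f.attrs["scanline_x_mm"], dtype=float)
            if "scanline_x_mm" in f.attrs
            else None,
        )


def write_delays(path, curve: DelayCurve) -> Path:
    """Delay curve → CSV (scanline, element, round1, round2, total) with a
    JSON summary sidecar carrying reference/gate metadata."""
    path = Path(path)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["scanline", "element", "round1", "round2", "total"])
        total = curve.total
        for s in range(curve.n_scanlines):
            for e in range(curve.n_elements):
                w.writerow([s, e, curve.round1[s], curve.round2[s, e], total[s, e]])
    summary = {
        "reference_scanline": int(curve.reference_scanline),
        "gate_mm": [curve.gate.z_min, curve.gate.z_max] if curve.gate else None,
        "n_substituted": int(curve.n_substituted),
        "n_scanlines": int(curve.n_scanlines),
        "n_elements": int(curve.n_elements),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(summary, indent=2))
    return path


def read_delays(path) -> DelayCurve:
    path = Path(path)
    rows = list(csv.DictReader(open(path)))
    S = max(int(r["scanline"]) for r in rows) + 1
    E = max(int(r["element"]) for r in rows) + 1
    round1 = np.zeros(S, dtype=np.int64)
    round2 = np.zeros((S, E), dtype=np.int64)
    for r in rows:
        s, e = int(r["scanline"]), int(r["element"])
        round1[s] = int(r["round1"])
        round2[s, e] = int(r["round2"])
    sidecar = path.with_suffix(path.suffix + ".json")
    ref, gate, n_sub = 0, None, 0
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        ref = int(meta.get("reference_scanline", 0))
        n_sub = int(meta.get("n_substituted", 0))
        if meta.get("gate_mm"):
            gate = GateWindow(*meta["gate_mm"])
    return DelayCurve(round1, round2, ref, gate, n_sub)


def save_png(path, image: BModeImage) -> Path:
    """8-bit grayscale PNG mapping [floor_db, 0] dB → [0, 255]."""
    path = Path(path)
    span = -image.floor_db
    norm = np.clip((image.pixels_db - image.floor_db) / span, 0.0, 1.0)
    Image.fromarray((norm * 255).astype(np.uint8), mode="L").save(path)
    return path


def write_image(path, image: BModeImage) -> Path:
    """Lossless HDF5 image container (dB pixels + axes)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("pixels_db", data=image.pixels_db)
        f.create_dataset("depth_mm", data=image.depth_mm)
        f.create_dataset("lateral_mm", data=image.lateral_mm)
        f.attrs["floor_db"] = image.floor_db
        f.attrs["provenance"] = image.provenance
    return path


def read_image(path) -> BModeImage:
    with h5py.File(path, "r") as f:
        return BModeImage(
            pixels_db=f["pixels_db"][()],
            depth_mm=f["depth_mm"][()],
            lateral_mm=f["lateral_mm"][()],
            floor_db=float(f.attrs["floor_db"]),
            provenance=str(f.attrs["provenance"]),
        )
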