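"""Volume container I/O: HDF5 layout, TIFF export, YAML scene files.

Container layout (HDF5):

    /displacement          complex dataset [z, x, y] (native paired real/imag)
    /acquisition_time      float [x, y], per-A-line sample time, s
    /grid                  group: dz, dx, dy attributes
    /protocol              group: the flat protocol mapping as attributes
    /provenance            group: seed, software version, scene hash
    root attrs             stage in {raw, coherent, kmap}; air_start/air_stop

Readers validate the stage tag so pipeline steps cannot be run out of order.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from . import __version__
from .protocol import ScanProtocol
from .wavefield import DisplacementVolume

__all__ = [
    "SchemaError",
    "write_volume",
    "read_volume",
    "export_tiff",
    "load_scene",
    "scene_hash",
    "write_kmap",
]

KNOWN_STAGES = ("raw", "coherent", "kmap")


class SchemaError(ValueError):
    """The container is missing required attributes or has an unknown stage."""


def scene_hash(scene: dict) -> str:
    """Stable hash of a scene mapping for provenance."""
    blob = json.dumps(scene, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_volume(vol: DisplacementVolume, path, *, provenance: dict | None = None) -> Path:
    """Write a displacement volume to the HDF5 container."""
    if vol.stage not in KNOWN_STAGES:
        raise SchemaError(f"unknown stage {vol.stage!r}")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("displacement", data=vol.S.astype(np.complex128))
        f.create_dataset("acquisition_time", data=vol.acquisition_time)
        g = f.create_group("grid")
        g.attrs["dz"] = vol.dz
        g.attrs["dx"] = vol.dx
        g.attrs["dy"] = vol.dy
        gp = f.create_group("protocol")
        for k, v in vol.protocol.to_dict().items():
            gp.attrs[k] = v
        gv = f.create_group("provenance")
        gv.attrs["software_version"] = __version__
        for k, v in (provenance or {}).items():
            gv.attrs[k] = v
        for k, v in vol.meta.items():
            if v is not None and np.isscalar(v):
                gv.attrs[f"meta_{k}"] = v
        f.attrs["stage"] = vol.stage
        if vol.wrap_scale is not None:
            f.attrs["wrap_scale"] = vol.wrap_scale
        if vol.air_rows is not None:
            f.attrs["air_start"] = vol.air_rows.start
            f.attrs["air_stop"] = vol.air_rows.stop
        if vol.truth is not None:
            f.create_dataset("truth", data=vol.truth.astype(np.complex128))
    return path


def read_volume(path, *, expect_stage: str | None = None) -> DisplacementVolume:
    """Read a displacement volume; optionally enforce the expected stage tag."""
    with h5py.File(path, "r") as f:
        missing = [k for k in ("displacement", "acquisition_time") if k not in f]
        if "protocol" not in f:
            missing.append("protocol")
        if "grid" not in f:
            missing.append("grid")
        if missing:
            raise SchemaError(f"container missing: {missing}")
        stage = str(f.attrs.get("stage", ""))
        if stage not in KNOWN_STAGES:
            raise SchemaError(f"unknown stage tag {stage!r}")
        if expect_stage is not None and stage != expect_stage:
            raise SchemaError(f"stage mismatch: file is {stage!r}, expected {expect_stage!r}")
        S = f["displacement"][()]
        T = f["acquisition_time"][()]
        g = {k: float(v) for k, v in f["grid"].attrs.items()}
        proto = ScanProtocol.from_dict(dict(f["protocol"].attrs))
        air = None
        if "air_start" in f.attrs:
            air = slice(int(f.attrs["air_start"]), int(f.attrs["air_stop"]))
        truth = f["truth"][()] if "truth" in f else None
        wrap_scale = float(f.attrs["wrap_scale"]) if "wrap_scale" in f.attrs else None
        meta = {k[5:]: v for k, v in f["provenance"].attrs.items() if k.startswith("meta_")}
    return DisplacementVolume(
        S=S, dz=float(g["dz"]), dx=float(g["dx"]), dy=float(g["dy"]),
        acquisition_time=T, protocol=proto, air_rows=air, truth=truth,
        stage=stage, wrap_scale=wrap_scale, meta=meta,
    )


def export_tiff(array: np.ndarray, path) -> Path:
    """Export a real 2D map as float32 TIFF (complex inputs export |.|)."""
    path = Path(path)
    a = np.asarray(array)
    if np.iscomplexobj(a):
        a = np.abs(a)
    tifffile.imwrite(path, a.astype(np.float32))
    return path


def write_kmap(kmap, path, *, f0_hz: float | None = None) -> Path:
    """Write a KMap (k/c/G + geometry) to HDF5 with stage tag 'kmap'."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("k", data=np.asarray(kmap.k, float))
        if kmap.c is not None:
            f.create_dataset("c", data=np.asarray(kmap.c, float))
        if kmap.G is not None:
            f.create_dataset("G", data=np.asarray(kmap.G, float))
        if kmap.window_x is not None:
            f.create_dataset("window_x", data=kmap.window_x)
            f.create_dataset("window_y", data=kmap.window_y)
        f.attrs["stage"] = "kmap"
        if f0_hz is not None:
            f.attrs["f0_hz"] = f0_hz
        for k, v in kmap.meta.items():
            if v is not None and np.isscalar(v):
                f.attrs[f"meta_{k}"] = v
    return path


def load_scene(path) -> dict:
    """Load a YAML scene file describing protocol, sources/components and noise."""
    with open(path) as fh:
        scene = yaml.safe_load(fh)
    if not isinstance(scene, dict):
        raise SchemaError("scene file must contain a mapping")
    if "protocol" not in scene:
        raise SchemaError("scene must contain a 'protocol' block")
    return scene
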