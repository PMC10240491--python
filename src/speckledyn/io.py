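"""HDF5 and JSON/CSV I/O for frame stacks, correlation curves and fits.

FrameStack schema (version 1):

* ``/frames``      uint photon counts, shape (n_frames, n_rows, n_cols)
* ``/timestamps``  float64 seconds
* ``/mask``        uint8, 1 = valid pixel
* root attributes: ``schema_version``, ``photon_energy_kev``, ``sdd_m``,
  ``pixel_size_um``, ``beam_center``, plus optional ``temperature_k``,
  ``flux_density`` and a JSON-encoded ``meta`` blob.

Synthetic stacks additionally get a sidecar ``<path>.truth.json`` with the
generator's ground-truth parameters so recovery tests can find them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .exceptions import SchemaError
from .geometry import DetectorGeometry
from .stacks import FrameStack

SCHEMA_VERSION = 1
_REQUIRED_ATTRS = ("schema_version", "photon_energy_kev", "sdd_m",
                   "pixel_size_um", "beam_center")
_REQUIRED_DSETS = ("frames", "timestamps", "mask")


def write_frame_stack(stack: FrameStack, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stack.images,
                         compression="gzip", compression_opts=1)
        f.create_dataset("timestamps", data=stack.timestamps)
        f.create_dataset("mask", data=stack.mask.astype(np.uint8))
        f.attrs["schema_version"] = SCHEMA_VERSION
        g = stack.geometry
        f.attrs["photon_energy_kev"] = g.photon_energy_kev
        f.attrs["sdd_m"] = g.sdd_m
        f.attrs["pixel_size_um"] = g.pixel_size_um
        f.attrs["beam_center"] = list(g.beam_center)
        if stack.temperature_k is not None:
            f.attrs["temperature_k"] = stack.temperature_k
        if stack.flux_density is not None:
            f.attrs["flux_density"] = stack.flux_density
        f.attrs["meta"] = json.dumps(stack.meta, default=_json_default)
    truth = stack.meta.get("truth")
    if truth is not None:
        with open(path.with_suffix(path.suffix + ".truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, default=_json_default)
    return path


def read_frame_stack(path) -> FrameStack:
    path = Path(path)
    with h5py.File(path, "r") as f:
        missing = [a for a in _REQUIRED_ATTRS if a not in f.attrs]
        missing += [d for d in _REQUIRED_DSETS if d not in f]
        if missing:
            raise SchemaError(
                f"{path.name}: not a frame-stack file; missing {missing}",
                missing=missing)
        geom = DetectorGeometry(
            photon_energy_kev=float(f.attrs["photon_energy_kev"]),
            sdd_m=float(f.attrs["sdd_m"]),
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            beam_center=tuple(np.asarray(f.attrs["beam_center"], dtype=float)),
            shape=tuple(int(s) for s in f["frames"].shape[1:]),
        )
        meta = json.loads(f.attrs.get("meta", "{}"))
        stack = FrameStack(
            images=f["frames"][...],
            timestamps=f["timestamps"][...],
            geometry=geom,
            mask=f["mask"][...].astype(bool),
            temperature_k=(float(f.attrs["temperature_k"])
                           if "temperature_k" in f.attrs else None),
            flux_density=(float(f.attrs["flux_density"])
                          if "flux_density" in f.attrs else None),
            meta=meta,
        )
    return stack


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def fit_to_json(fit, path) -> Path:
    """Serialize any fit dataclass (parameters, SEs, diagnostics) to JSON."""
    path = Path(path)
    d = dataclasses.asdict(fit)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, default=_json_default)
    return path


def g2_to_csv(curve, path) -> Path:
    import pandas as pd
    path = Path(path)
    df = pd.DataFrame({"lag_s": curve.lags, "g2": curve.g2, "se": curve.se})
    with open(path, "w") as fh:
        fh.write(f"# g2 at Q = {curve.q:.6g} 1/nm; lags in seconds; "
                 f"{curve.n_pixels} pixels, {curve.n_frames} frames\n")
        df.to_csv(fh, index=False)
    return path


def g2_to_hdf5(curve, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("g2", data=curve.g2)
        f.create_dataset("lags", data=curve.lags)
        f.create_dataset("errors", data=curve.se)
        f.attrs["q_nm^-1"] = curve.q
        f.attrs["n_pixels"] = curve.n_pixels
        f.attrs["n_frames"] = curve.n_frames
    return path


def ttc_to_hdf5(ttc, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("ttc", data=ttc.matrix, compression="gzip",
                         compression_opts=1)
        f.create_dataset("times", data=ttc.times)
        f.attrs["q_nm^-1"] = ttc.q
        f.attrs["n_pixels"] = ttc.n_pixels
    return path
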