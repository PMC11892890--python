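"""Readers and writers for volumes and projection/sinogram stacks.

Two on-disk forms are supported, chosen by file suffix:

* multi-page TIFF (``.tif``/``.tiff``): one 32-bit float page per Z slice
  (volumes), per angle (projections) or per detector row (sinograms);
  angles are stored in degrees in the TIFF description tag.
* HDF5 (``.h5``/``.hdf5``): datasets ``volume``, ``projections`` or
  ``sinograms`` with an ``angles_deg`` attribute.

Angles are degrees on disk, radians in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .phantom import Volume
from .pipeline import ProjectionStack, SinogramStack

__all__ = [
    "write_volume",
    "read_volume",
    "write_projections",
    "read_projections",
    "write_sinograms",
    "read_sinograms",
]

_TIFF = {".tif", ".tiff"}
_HDF5 = {".h5", ".hdf5"}


def _suffix(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix not in _TIFF | _HDF5:
        raise ValueError(f"unsupported file type {suffix!r}; use TIFF or HDF5")
    return suffix


def _write_stack(path, data: np.ndarray, dataset: str, angles=None) -> None:
    data = np.asarray(data, dtype=np.float32)
    meta = {"dataset": dataset}
    if angles is not None:
        meta["angles_deg"] = list(np.degrees(angles))
    if _suffix(path) in _TIFF:
        tifffile.imwrite(path, data, description=json.dumps(meta))
    else:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset, data=data)
            if angles is not None:
                ds.attrs["angles_deg"] = np.degrees(angles)


def _read_stack(path, dataset: str) -> tuple[np.ndarray, np.ndarray | None]:
    if _suffix(path) in _TIFF:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        angles = None
        if desc:
            try:
                meta = json.loads(desc)
                if "angles_deg" in meta:
                    angles = np.radians(meta["angles_deg"])
            except (json.JSONDecodeError, TypeError):
                pass
        return np.asarray(data, dtype=np.float32), angles
    with h5py.File(path, "r") as f:
        if dataset not in f:
            raise KeyError(f"dataset {dataset!r} not found in {path}")
        ds = f[dataset]
        angles = None
        if "angles_deg" in ds.attrs:
            angles = np.radians(np.asarray(ds.attrs["angles_deg"]))
        return np.asarray(ds[()], dtype=np.float32), angles


def write_paired_scan(path, scan) -> None:
    """Store a paired LQ/HQ scan as one HDF5 file.

    Datasets ``projections_lq`` and ``projections_hq`` with ``angles_deg``
    attributes; the HQ reconstruction is recomputed on load.
    """
    if _suffix(path) not in _HDF5:
        raise ValueError("paired scans are stored as HDF5")
    with h5py.File(path, "w") as f:
        for name, stack in (("projections_lq", scan.p_lq), ("projections_hq", scan.p_hq)):
            ds = f.create_dataset(name, data=stack.data.astype(np.float32))
            ds.attrs["angles_deg"] = np.degrees(stack.angles)


def read_paired_scan(path):
    from .training import PairedScan

    with h5py.File(path, "r") as f:
        stacks = {}
        for name in ("projections_lq", "projections_hq"):
            ds = f[name]
            stacks[name] = ProjectionStack(
                np.asarray(ds[()], dtype=np.float32),
                np.radians(np.asarray(ds.attrs["angles_deg"])),
            )
    return PairedScan(p_lq=stacks["projections_lq"], p_hq=stacks["projections_hq"])


def write_volume(path, vol: Volume) -> None:
    _write_stack(path, vol.data, "volume")


def read_volume(path) -> Volume:
    data, _ = _read_stack(path, "volume")
    return Volume(data)


def write_projections(path, p: ProjectionStack) -> None:
    _write_stack(path, p.data, "projections", p.angles)


def read_projections(path) -> ProjectionStack:
    data, angles = _read_stack(path, "projections")
    if angles is None:
        raise ValueError(f"{path} carries no angle metadata")
    return ProjectionStack(data, angles)


def write_sinograms(path, s: SinogramStack) -> None:
    _write_stack(path, s.data, "sinograms", s.angles)


def read_sinograms(path) -> SinogramStack:
    data, angles = _read_stack(path, "sinograms")
    if angles is None:
        raise ValueError(f"{path} carries no angle metadata")
    return SinogramStack(data, angles)
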