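"""File I/O: HDF5 ensemble containers, YAML configs, tidy CSV tables.

Ensembles are stored in a simple hierarchical layout — ``/rf`` with shape
(frames, axial, lateral) and ``/meta`` attributes mirroring the acquisition
geometry — documented here because vendor formats are proprietary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import yaml

from .acquisition import ROI, AcquisitionGeometry, EnsembleStack

_GEOMETRY_FIELDS = [f.name for f in dataclasses.fields(AcquisitionGeometry)]


def write_ensemble(path, ens: EnsembleStack) -> None:
    """Write one ensemble to an HDF5 container (/rf + /meta attrs)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("rf", data=ens.frames)
        meta = h5.create_group("meta")
        for name in _GEOMETRY_FIELDS:
            meta.attrs[name] = getattr(ens.geometry, name)
        meta.attrs["slow_time_rate_hz"] = ens.slow_time_rate_hz
        for k, v in ens.provenance.items():
            if isinstance(v, (str, int, float, bool, np.integer, np.floating)):
                meta.attrs[f"prov_{k}"] = v


def read_ensemble(path) -> EnsembleStack:
    """Read an ensemble written by `write_ensemble`."""
    with h5py.File(path, "r") as h5:
        frames = np.asarray(h5["rf"])
        meta = h5["meta"].attrs
        kwargs = {}
        for f in dataclasses.fields(AcquisitionGeometry):
            v = meta[f.name]
            kwargs[f.name] = int(v) if f.type == "int" else float(v)
        geom = AcquisitionGeometry(**kwargs)
        prov = {
            k[len("prov_"):]: (v.item() if hasattr(v, "item") else v)
            for k, v in meta.items() if k.startswith("prov_")
        }
        return EnsembleStack(
            frames=frames,
            geometry=geom,
            slow_time_rate_hz=float(meta["slow_time_rate_hz"]),
            provenance=prov,
        )


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def geometry_from_config(cfg: dict) -> AcquisitionGeometry:
    """Build a geometry from a config's ``geometry`` section (all optional)."""
    params = dict(cfg.get("geometry", {}))
    unknown = set(params) - set(_GEOMETRY_FIELDS)
    if unknown:
        raise ValueError(f"unknown geometry fields: {sorted(unknown)}")
    return AcquisitionGeometry(**params)


def rois_from_config(cfg: dict, geom: AcquisitionGeometry) -> list[ROI]:
    """Parse the ``rois`` section: list of axial/lateral/height/width in mm."""
    from .acquisition import default_rois

    entries = cfg.get("rois")
    if not entries:
        return default_rois(geom)
    rois = []
    for e in entries:
        roi = ROI(
            axial_mm=float(e["axial_mm"]),
            lateral_mm=float(e["lateral_mm"]),
            height_mm=float(e.get("height_mm", 1.0)),
            width_mm=float(e.get("width_mm", 1.0)),
        )
        roi.to_slices(geom)
        rois.append(roi)
    return rois


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
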