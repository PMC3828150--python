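"""Readers and writers for the package's external formats.

Spike rasters: two-column plain text ``time_s  neuron_id`` (and an HDF5
container for long runs).  Weight matrices: Matrix Market sparse coordinate
format (1-based indices) with a YAML sidecar carrying run metadata.  Run
configurations: flat ``key: value`` YAML files whose keys mirror the
parameter-table field names; keys are routed to the parameter dataclasses by
name.
"""
from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path
from typing import Dict, Optional, Tuple

import h5py
import numpy as np
import scipy.io as sio
import scipy.sparse as sp
import yaml

from . import __version__
from .params import (NetworkConfig, NeuronParams, TripletParams,
                     HomeostasisConfig, ConfigurationError)
from .spikenet import SpikeRaster

__all__ = [
    "save_raster_text", "load_raster_text",
    "save_raster_h5", "load_raster_h5",
    "save_weights_mtx", "load_weights_mtx",
    "load_config", "split_config", "run_stamp",
]


def save_raster_text(path, raster: SpikeRaster) -> None:
    header = (f"homeoplast raster: duration={raster.duration} "
              f"n_exc={raster.n_exc_total} n_inh={raster.n_inh_total} "
              f"rec_exc={raster.n_exc_recorded} rec_inh={raster.n_inh_recorded}")
    np.savetxt(path, np.column_stack([raster.times, raster.ids]),
               fmt="%.6f %d", header=header)


def load_raster_text(path) -> Tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    return data[:, 0], data[:, 1].astype(np.int64)


def save_raster_h5(path, raster: SpikeRaster) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=raster.times, compression="gzip")
        f.create_dataset("ids", data=raster.ids, compression="gzip")
        for k in ("duration", "n_exc_total", "n_inh_total",
                  "n_exc_recorded", "n_inh_recorded"):
            f.attrs[k] = getattr(raster, k)
        f.attrs["version"] = __version__


def load_raster_h5(path) -> SpikeRaster:
    with h5py.File(path, "r") as f:
        return SpikeRaster(times=f["times"][:], ids=f["ids"][:],
                           duration=float(f.attrs["duration"]),
                           n_exc_total=int(f.attrs["n_exc_total"]),
                           n_inh_total=int(f.attrs["n_inh_total"]),
                           n_exc_recorded=int(f.attrs["n_exc_recorded"]),
                           n_inh_recorded=int(f.attrs["n_inh_recorded"]))


def save_weights_mtx(path, weights: sp.spmatrix,
                     metadata: Optional[Dict] = None) -> None:
    """Write a sparse weight matrix in Matrix Market coordinate format
    (1-based indices) plus a ``<path>.meta.yaml`` sidecar."""
    path = Path(path)
    sio.mmwrite(str(path), sp.coo_matrix(weights))
    meta = dict(metadata or {})
    meta.setdefault("written", datetime.datetime.now().isoformat(timespec="seconds"))
    meta.setdefault("version", run_stamp())
    with open(str(path) + ".meta.yaml", "w") as f:
        yaml.safe_dump(meta, f)


def load_weights_mtx(path) -> sp.csr_matrix:
    return sp.csr_matrix(sio.mmread(str(path)))


_PARAM_CLASSES = (NetworkConfig, NeuronParams, TripletParams, HomeostasisConfig)


def load_config(path) -> Dict:
    """Read a flat key: value configuration file."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config file must be a flat key: value mapping")
    return cfg


def split_config(cfg: Dict) -> Tuple[NetworkConfig, NeuronParams,
                                     TripletParams, HomeostasisConfig]:
    """Route flat config keys to the four parameter dataclasses by field
    name; unknown keys raise."""
    buckets = {cls: {} for cls in _PARAM_CLASSES}
    fields = {cls: {f.name for f in dataclasses.fields(cls)}
              for cls in _PARAM_CLASSES}
    for key, value in cfg.items():
        hit = False
        for cls in _PARAM_CLASSES:
            if key in fields[cls]:
                buckets[cls][key] = value
                hit = True
        if not hit:
            raise ConfigurationError(f"unknown configuration key {key!r}")
    return (NetworkConfig(**buckets[NetworkConfig]),
            NeuronParams(**buckets[NeuronParams]),
            TripletParams(**buckets[TripletParams]),
            HomeostasisConfig(**buckets[HomeostasisConfig]))


def run_stamp() -> str:
    return f"homeoplast-{__version__}"
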