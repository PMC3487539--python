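"""Spike-data file I/O.

Plain-text format: two tab-separated columns ``neuron_id<TAB>time_ms``,
sorted by time, with a JSON sidecar (``<path>.meta.json``) holding the
duration, the number of neurons, the population labels and provenance
metadata.  An optional HDF5 container (``/spikes/ids``, ``/spikes/times``,
``/meta``) is available when h5py is installed.

Times are stored with 0.1 ms resolution (one decimal), matching the
simulator grid; the round trip is lossless for grid-aligned data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import InputError
from .netsim import SpikeData

__all__ = ["read_spikes", "write_spikes"]

_META_SUFFIX = ".meta.json"


def _meta_path(path: Path) -> Path:
    return Path(str(path) + _META_SUFFIX)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_spikes(spikes: SpikeData, path: str | Path) -> None:
    """Write spike data as TSV plus JSON sidecar (or HDF5 for .h5/.hdf5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_hdf5(spikes, path)
        return
    with open(path, "w") as fh:
        for i, t in zip(spikes.ids, spikes.times):
            fh.write(f"{i}\t{t:.1f}\n")
    meta = {
        "duration": spikes.duration,
        "n_neurons": int(spikes.n_neurons),
        "labels": "".join(spikes.labels),
        "meta": _jsonable(spikes.meta),
    }
    with open(_meta_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_spikes(path: str | Path) -> SpikeData:
    """Read spike data written by :func:`write_spikes`.

    Malformed, unsorted or out-of-range records are rejected with the
    offending line number.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_hdf5(path)
    mpath = _meta_path(path)
    if not mpath.exists():
        raise InputError(f"missing sidecar metadata file {mpath}")
    with open(mpath) as fh:
        meta = json.load(fh)
    ids, times = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected two "
                                 f"tab-separated columns, got {line!r}")
            try:
                i, t = int(parts[0]), float(parts[1])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
            if times and t < times[-1]:
                raise InputError(f"{path}:{lineno}: spike times not sorted")
            if not (0.0 <= t < meta["duration"]):
                raise InputError(
                    f"{path}:{lineno}: time {t} outside [0, duration)")
            ids.append(i)
            times.append(t)
    labels = meta["labels"]
    is_inh = np.array([c == "I" for c in labels], dtype=bool)
    return SpikeData(ids=np.array(ids, dtype=np.int64),
                     times=np.array(times),
                     duration=float(meta["duration"]),
                     n_neurons=int(meta["n_neurons"]),
                     is_inh=is_inh, meta=meta.get("meta", {}))


def _write_hdf5(spikes: SpikeData, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        grp = fh.create_group("spikes")
        grp.create_dataset("ids", data=spikes.ids)
        grp.create_dataset("times", data=spikes.times)
        meta = fh.create_group("meta")
        meta.attrs["duration"] = spikes.duration
        meta.attrs["n_neurons"] = spikes.n_neurons
        meta.attrs["labels"] = "".join(spikes.labels)
        meta.attrs["json"] = json.dumps(_jsonable(spikes.meta))


def _read_hdf5(path: Path) -> SpikeData:
    import h5py

    with h5py.File(path, "r") as fh:
        ids = fh["spikes/ids"][()]
        times = fh["spikes/times"][()]
        meta = fh["meta"]
        labels = meta.attrs["labels"]
        return SpikeData(ids=ids, times=times,
                         duration=float(meta.attrs["duration"]),
                         n_neurons=int(meta.attrs["n_neurons"]),
                         is_inh=np.array([c == "I" for c in labels]),
                         meta=json.loads(meta.attrs["json"]))
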