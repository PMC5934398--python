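"""Ensemble container I/O: HDF5 and CSV-directory dialects.

Both dialects round-trip a :class:`~sgckit.ensemble.TrialEnsemble`
bit-for-bit (CSV values are written with 17 significant digits, which
round-trips IEEE doubles exactly). File schemas carry a ``schema_version``
field.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from sgckit.ensemble import TrialEnsemble

SCHEMA_VERSION = 1

REQUIRED_KEYS = ("data", "sampling_rate", "channel_labels", "areas", "conditions")


class SchemaError(ValueError):
    """Raised when a container is missing required datasets or metadata."""

    def __init__(self, missing: list[str], where: str):
        self.missing = list(missing)
        super().__init__(f"{where}: missing required keys {self.missing}")


def write_ensemble(ensemble: TrialEnsemble, path: str | Path) -> Path:
    """Write an ensemble to ``path``.

    ``.h5``/``.hdf5`` suffixes select the HDF5 dialect; any other path is
    treated as a directory of per-channel CSV matrices plus a JSON metadata
    sidecar.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _write_hdf5(ensemble, path)
    return _write_csv_dir(ensemble, path)


def read_ensemble(path: str | Path) -> TrialEnsemble:
    path = Path(path)
    if path.is_dir():
        return _read_csv_dir(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_hdf5(path)
    raise ValueError(f"cannot infer container dialect for {path}")


# -- HDF5 -------------------------------------------------------------------

def _write_hdf5(ensemble: TrialEnsemble, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ensemble.data)
        f.create_dataset(
            "channel_labels",
            data=np.array(ensemble.channel_labels, dtype=h5py.string_dtype()),
        )
        f.create_dataset(
            "areas",
            data=np.array(
                [ensemble.areas[c] for c in ensemble.channel_labels],
                dtype=h5py.string_dtype(),
            ),
        )
        f.create_dataset(
            "conditions",
            data=np.array(list(ensemble.conditions), dtype=h5py.string_dtype()),
        )
        f.attrs["sampling_rate"] = float(ensemble.sampling_rate)
        f.attrs["schema_version"] = SCHEMA_VERSION
    return path


def _read_hdf5(path: Path) -> TrialEnsemble:
    with h5py.File(path, "r") as f:
        missing = [k for k in ("data", "channel_labels", "areas", "conditions") if k not in f]
        if "sampling_rate" not in f.attrs:
            missing.append("sampling_rate")
        if missing:
            raise SchemaError(missing, str(path))
        labels = [s.decode() if isinstance(s, bytes) else s for s in f["channel_labels"][()]]
        areas_list = [s.decode() if isinstance(s, bytes) else s for s in f["areas"][()]]
        conditions = np.array(
            [s.decode() if isinstance(s, bytes) else s for s in f["conditions"][()]],
            dtype=object,
        )
        return TrialEnsemble(
            data=f["data"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            channel_labels=labels,
            areas=dict(zip(labels, areas_list)),
            conditions=conditions,
        )


# -- CSV directory ----------------------------------------------------------

def _write_csv_dir(ensemble: TrialEnsemble, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    for i, label in enumerate(ensemble.channel_labels):
        np.savetxt(
            path / f"data_{label}.csv",
            ensemble.data[:, i, :],
            delimiter=",",
            fmt="%.17g",
        )
    meta = {
        "schema_version": SCHEMA_VERSION,
        "sampling_rate": float(ensemble.sampling_rate),
        "channel_labels": ensemble.channel_labels,
        "areas": {c: ensemble.areas[c] for c in ensemble.channel_labels},
        "conditions": list(ensemble.conditions),
        "n_trials": ensemble.n_trials,
        "n_samples": ensemble.n_samples,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))
    return path


def _read_csv_dir(path: Path) -> TrialEnsemble:
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise SchemaError(["metadata.json"], str(path))
    meta = json.loads(meta_path.read_text())
    missing = [
        k for k in ("sampling_rate", "channel_labels", "areas", "conditions")
        if k not in meta
    ]
    if missing:
        raise SchemaError(missing, str(meta_path))
    labels = meta["channel_labels"]
    n_trials = int(meta.get("n_trials", 0))
    n_samples = int(meta.get("n_samples", 0))
    channels = []
    for label in labels:
        fp = path / f"data_{label}.csv"
        if not fp.exists():
            raise SchemaError([fp.name], str(path))
        arr = np.loadtxt(fp, delimiter=",", ndmin=2)
        if arr.size == 0:
            arr = arr.reshape(n_trials, n_samples)
        channels.append(arr)
    data = np.stack(channels, axis=1)
    return TrialEnsemble(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=list(labels),
        areas=dict(meta["areas"]),
        conditions=np.array(meta["conditions"], dtype=object),
    )
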