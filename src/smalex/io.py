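"""File formats: photon HDF5/CSV, burst tables, fit JSON, run configuration.

Photon HDF5 layout (modelled on the Photon-HDF5 convention, version field in
``/meta``):

    /photons/timestamps  int64, alternation-clock ticks (µs here)
    /photons/channel     uint8 detector code (0 donor, 1 acceptor)
    /meta                attrs: format_version, alternation_period,
                         seed (optional), config_hash (optional)

A plain CSV fallback (columns ``timestamp,channel``) serves tiny fixtures.
Every pipeline run emits a provenance record (config hash, seed, package
version) so results are reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .bursts import BURST_COLUMNS, PhotonStream

PHOTON_HDF5_VERSION = "1.0"


class SchemaError(ValueError):
    """A file does not match the documented schema."""


# ---------------------------------------------------------------- photons

def write_photons_hdf5(path, stream: PhotonStream, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("photons")
        g.create_dataset("timestamps", data=stream.timestamps.astype(np.int64))
        g.create_dataset("channel", data=stream.detector.astype(np.uint8))
        m = f.create_group("meta")
        m.attrs["format_version"] = PHOTON_HDF5_VERSION
        m.attrs["alternation_period"] = stream.alternation_period
        for k, v in (meta or {}).items():
            m.attrs[k] = v


def read_photons_hdf5(path) -> PhotonStream:
    with h5py.File(path, "r") as f:
        try:
            ts = f["photons/timestamps"][()]
            ch = f["photons/channel"][()]
            period = int(f["meta"].attrs["alternation_period"])
        except KeyError as exc:
            raise SchemaError(f"photon HDF5 missing field: {exc}") from exc
    order = np.argsort(ts, kind="stable")
    return PhotonStream(ts[order], ch[order], alternation_period=period)


def write_photons_csv(path, stream: PhotonStream) -> None:
    pd.DataFrame(
        {"timestamp": stream.timestamps, "channel": stream.detector}
    ).to_csv(path, index=False)


def read_photons_csv(path, alternation_period: int = 50) -> PhotonStream:
    """Read a photon CSV; rows are sorted on load, malformed rows reported."""
    df = pd.read_csv(path)
    for col in ("timestamp", "channel"):
        if col not in df.columns:
            raise SchemaError(f"photon CSV missing column {col!r}")
    n_raw = len(df)
    df = df.dropna(subset=["timestamp", "channel"])
    bad = df["channel"].astype(int).isin([0, 1]) == False  # noqa: E712
    n_malformed = n_raw - len(df) + int(bad.sum())
    if n_malformed:
        warnings.warn(f"dropped {n_malformed} malformed photon row(s)", RuntimeWarning)
    df = df.loc[~bad].sort_values("timestamp", kind="stable")
    if df.empty:
        warnings.warn("photon file contains no photons", RuntimeWarning)
    return PhotonStream(
        df["timestamp"].to_numpy(dtype=np.int64),
        df["channel"].to_numpy(dtype=np.uint8),
        alternation_period=alternation_period,
    )


def read_photons(path, alternation_period: int = 50) -> PhotonStream:
    """Dispatch on extension: .h5/.hdf5 -> HDF5 layout, otherwise CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        return read_photons_hdf5(path)
    return read_photons_csv(path, alternation_period=alternation_period)


def write_photons(path, stream: PhotonStream, meta: dict | None = None) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        write_photons_hdf5(path, stream, meta)
    else:
        write_photons_csv(path, stream)


# ---------------------------------------------------------------- bursts / fits

def write_bursts_csv(path, bursts: pd.DataFrame) -> None:
    bursts.to_csv(path, index=False, columns=[c for c in BURST_COLUMNS if c in bursts])


def read_bursts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"f_dd", "f_da", "f_aa"} - set(df.columns)
    if missing:
        raise SchemaError(f"burst CSV missing column(s): {sorted(missing)}")
    return df


def write_json(path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------- config

def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping (provenance record)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path, known_keys: set[str] | None = None) -> dict:
    """Load a YAML run configuration; unknown top-level keys are rejected."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise SchemaError("config file must contain a mapping")
    if known_keys is not None:
        unknown = set(cfg) - known_keys
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    return cfg


def provenance(config: dict, seed: int | None) -> dict:
    from . import __version__

    return {
        "config_hash": config_hash(config),
        "seed": seed,
        "smalex_version": __version__,
    }
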