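"""HDF5 session containers, channel-map CSVs and run configuration.

Layout of a session file (schema version 1):

    /raw      (channels × time)            — continuous voltage
    /epochs   (events × channels × samples) — epoched observations
    /latents  (events × channels × samples) — posterior-mean log-volatility
    /power    (events × channels × freqs)   — log, epoch-averaged power
    /events   onsets, recalled, session     — event metadata
    attrs: fs, subject, session, schema_version, indexing ("0-based,
    half-open"), per-dataset units

Channel metadata travels as a companion CSV with columns
channel,region,hemisphere; run configuration as JSON validated against
:class:`RunConfig` (unknown keys rejected).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .core import MSVParams
from .preprocessing import EpochedData, RawSession

__all__ = ["RunConfig", "write_session", "read_session",
           "write_channel_map", "read_channel_map",
           "save_params_json", "load_params_json"]

SCHEMA_VERSION = 1


class MCMCSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_iter: int = 5000
    burn_in: int = 1000
    latent_thin: int = 10
    diagonal: bool = False


class PreprocSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    notch_center: float = 60.0
    notch_width: float = 5.0
    notch_order: int = 4
    window_s: float = 1.6
    p_max: int = 10


class PriorSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mu_prior_var: float = 1000.0
    beta_a: float = 20.0
    beta_b: float = 1.5
    sigma_gamma_shape: float = 0.5
    sigma_gamma_rate: float = 0.05


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    preprocessing: PreprocSettings = PreprocSettings()
    prior: PriorSettings = PriorSettings()
    mcmc: MCMCSettings = MCMCSettings()
    freq_min: float = 3.0
    freq_max: float = 180.0
    freq_step: float = 1.0
    penalty_grid: list[float] = [10.0 ** e for e in range(-4, 5)]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


def _channel_map_path(path: Path) -> Path:
    return path.with_suffix(".channels.csv")


def write_channel_map(meta: pd.DataFrame, path: str | Path) -> None:
    cols = ["channel", "region", "hemisphere"]
    meta[cols].to_csv(path, index=False)


def read_channel_map(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    if "region" not in meta.columns:
        raise ValueError(f"channel map {path} lacks a region column")
    bad = meta.loc[meta["region"].isna(), "channel"].tolist()
    if bad:
        raise ValueError(f"channel map {path}: channels missing region: {bad}")
    return meta


def write_session(obj: RawSession | EpochedData, path: str | Path,
                  config: RunConfig | None = None) -> None:
    """Write a raw or epoched session plus its companion channel-map CSV."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["indexing"] = "0-based, half-open"
        f.attrs["fs"] = float(obj.fs)
        if config is not None:
            f.attrs["run_config"] = config.model_dump_json()
        if isinstance(obj, RawSession):
            d = f.create_dataset("raw", data=obj.samples)
            d.attrs["units"] = "uV"
            d.attrs["axes"] = "channels x time"
            f.create_dataset("events/onsets", data=obj.event_onsets)
            labels = obj.event_labels
        else:
            d = f.create_dataset("epochs", data=obj.data)
            d.attrs["units"] = "uV (detrended)"
            d.attrs["axes"] = "events x channels x samples"
            labels = obj.labels
        f.create_dataset("events/recalled",
                         data=labels["recalled"].to_numpy().astype(np.int8))
        f.create_dataset(
            "events/session",
            data=np.asarray(labels["session"]).astype("S16"))
    meta = obj.channel_meta if isinstance(obj, RawSession) else obj.channel_meta
    write_channel_map(meta, _channel_map_path(path))


def read_session(path: str | Path) -> RawSession | EpochedData:
    """Read a session container back into its typed object."""
    path = Path(path)
    meta = read_channel_map(_channel_map_path(path))
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {version}, "
                             f"expected {SCHEMA_VERSION}")
        if "fs" not in f.attrs:
            raise ValueError(f"{path}: fs attribute is missing")
        fs = float(f.attrs["fs"])
        sessions = f["events/session"][()].astype(str)
        labels = pd.DataFrame({
            "recalled": f["events/recalled"][()].astype(bool),
            "session": sessions,
        })
        if "raw" in f:
            raw = f["raw"][()]
            if raw.shape[0] != len(meta):
                raise ValueError(
                    f"{path}: raw has {raw.shape[0]} channels but the channel "
                    f"map lists {len(meta)}")
            return RawSession(samples=raw, fs=fs, channel_meta=meta,
                              event_onsets=f["events/onsets"][()],
                              event_labels=labels)
        if "epochs" in f:
            data = f["epochs"][()]
            if data.shape[1] != len(meta):
                raise ValueError(
                    f"{path}: epochs have {data.shape[1]} channels but the "
                    f"channel map lists {len(meta)}")
            return EpochedData(data=data, fs=fs, labels=labels,
                               channel_meta=meta)
    raise ValueError(f"{path}: neither /raw nor /epochs present")


def save_params_json(params: MSVParams, path: str | Path) -> None:
    Path(path).write_text(params.to_json())


def load_params_json(path: str | Path) -> MSVParams:
    return MSVParams.from_json(Path(path).read_text())
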