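"""File formats and run configuration.

Long-format CSV is the interchange format for all time series
(time_s, channel, wavelength_nm | chromophore, value), plus events,
ratings and results tables.  A minimal SNIRF-style HDF5 reader/writer
covers the standard layout (intensity + probe + stim).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import ALL_ITEMS, RatingMatrix
from .optics import HemoSeries, Montage, RawRecording, default_montage

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "write_recording_csv",
    "read_recording_csv",
    "write_events_csv",
    "read_events_csv",
    "write_ratings_csv",
    "read_ratings_csv",
    "write_hemo_csv",
    "read_hemo_csv",
    "write_snirf",
    "read_snirf",
    "read_recording",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline settings; every random stage has its own seed."""

    outdir: str = "results"
    seed: int = 0
    n_participants: int = 13
    fs: float = 50.0
    filter_low_hz: float = 0.01
    filter_high_hz: float = 0.2
    baseline_window_s: float = 10.0
    sample_window_s: float = 10.0
    n_sample_windows: int = 3
    svm_c: float = 1.0
    n_shuffles: int = 100
    top_k_clips: int = 6
    extinction_config: str | None = None
    min_duration_s: float = 30.0
    max_duration_s: float = 129.0
    with_permutation: bool = True

    def __post_init__(self) -> None:
        for name in ("fs", "filter_low_hz", "filter_high_hz", "baseline_window_s",
                     "sample_window_s", "svm_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------

def write_recording_csv(rec: RawRecording, path: str) -> None:
    """Long format: time_s, channel, wavelength_nm, intensity."""
    nw, nc, nt = rec.intensity.shape
    t = np.arange(nt) / rec.fs
    idx = pd.MultiIndex.from_product(
        [rec.wavelengths_nm, rec.montage.channel_id, t],
        names=["wavelength_nm", "channel", "time_s"],
    )
    df = pd.DataFrame({"intensity": rec.intensity.ravel()}, index=idx).reset_index()
    df[["time_s", "channel", "wavelength_nm", "intensity"]].to_csv(path, index=False)


def read_recording_csv(
    path: str, events: pd.DataFrame, montage: Montage | None = None
) -> RawRecording:
    """Read and validate a long-format intensity CSV.

    Checks: the channel x wavelength grid is complete, time is uniform and
    monotone, and all intensities are positive.
    """
    df = pd.read_csv(path)
    required = {"time_s", "channel", "wavelength_nm", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"recording CSV needs columns {sorted(required)}")
    wl = np.sort(df["wavelength_nm"].unique())
    ch = np.sort(df["channel"].unique())
    times = np.sort(df["time_s"].unique())
    if len(df) != len(wl) * len(ch) * len(times):
        # find one missing combination for the message
        have = set(zip(df["wavelength_nm"], df["channel"]))
        for w in wl:
            for c in ch:
                if (w, c) not in have:
                    raise ValueError(f"missing wavelength {w} nm / channel {c} series")
        raise ValueError("incomplete channel x wavelength x time grid")
    dt = np.diff(times)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time axis must be uniformly increasing")
    if (df["intensity"] <= 0).any():
        bad = df[df["intensity"] <= 0].iloc[0]
        raise ValueError(
            f"non-positive intensity at t={bad['time_s']} s, channel "
            f"{bad['channel']}, wavelength {bad['wavelength_nm']} nm"
        )
    cube = (
        df.pivot_table(
            index=["wavelength_nm", "channel"], columns="time_s", values="intensity"
        )
        .to_numpy()
        .reshape(len(wl), len(ch), len(times))
    )
    if montage is None:
        montage = default_montage(len(ch))
    fs = 1.0 / dt[0]
    return RawRecording(
        intensity=cube, wavelengths_nm=wl, fs=fs, montage=montage, events=events
    )


def write_events_csv(events: pd.DataFrame, path: str) -> None:
    events[["clip_id", "onset_s", "offset_s", "condition"]].to_csv(path, index=False)


def read_events_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"clip_id", "onset_s", "offset_s", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"events CSV needs columns {sorted(required)}")
    return df


def write_hemo_csv(hemo: HemoSeries, path: str) -> None:
    hemo.to_frame().to_csv(path, index=False)


def read_hemo_csv(path: str) -> HemoSeries:
    df = pd.read_csv(path)
    ch = np.sort(df["channel"].unique())
    times = np.sort(df["time_s"].unique())
    dt = np.diff(times)
    arrs = {}
    for chrom in ("HbO", "HbR"):
        sub = df[df["chromophore"] == chrom]
        arrs[chrom] = (
            sub.pivot_table(index="channel", columns="time_s", values="conc_um")
            .loc[ch]
            .to_numpy()
        )
    return HemoSeries(
        hbo=arrs["HbO"], hbr=arrs["HbR"], fs=1.0 / dt[0], channel_id=ch
    )


def write_ratings_csv(ratings: RatingMatrix, path: str) -> None:
    ratings.to_frame().to_csv(path, index=False)


def read_ratings_csv(path: str, clips: pd.DataFrame) -> RatingMatrix:
    """Rebuild a rating matrix from long format (participant, clip, item, value)."""
    df = pd.read_csv(path)
    participants = sorted(df["participant"].unique())
    items = [i for i in ALL_ITEMS if i in set(df["item"])]
    cube = (
        df.pivot_table(index=["participant", "clip"], columns="item", values="value")[
            list(items)
        ]
        .to_numpy()
        .reshape(len(participants), -1, len(items))
    )
    # order clips to match the metadata table
    clip_order = {c: i for i, c in enumerate(sorted(df["clip"].unique()))}
    perm = [clip_order[c] for c in clips["clip_id"]]
    return RatingMatrix(
        values=cube[:, perm, :],
        participants=participants,
        clips=clips.reset_index(drop=True),
        items=tuple(items),
    )


# ---------------------------------------------------------------------------
# SNIRF (HDF5)
# ---------------------------------------------------------------------------

def write_snirf(rec: RawRecording, path: str) -> None:
    """Write the standard SNIRF layout: intensity + probe + stim."""
    nw, nc, nt = rec.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        # columns: one measurement per (wavelength, channel)
        series = rec.intensity.reshape(nw * nc, nt).T
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.arange(nt) / rec.fs)
        m = 1
        for w in range(nw):
            for c in range(nc):
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=int(rec.montage.source_id[c]))
                ml.create_dataset("detectorIndex", data=int(rec.montage.detector_id[c]))
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                m += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=rec.wavelengths_nm)
        probe.create_dataset(
            "sourceDetectorSeparation_mm", data=rec.montage.separation_mm
        )
        for i, (_, ev) in enumerate(rec.events.iterrows(), start=1):
            stim = nirs.create_group(f"stim{i}")
            stim.create_dataset("name", data=str(ev["clip_id"]))
            stim.create_dataset(
                "data",
                data=np.array(
                    [[ev["onset_s"], ev["offset_s"] - ev["onset_s"], 1.0]]
                ),
            )
            stim.create_dataset("condition", data=str(ev["condition"]))


def read_snirf(path: str) -> RawRecording:
    """Read the SNIRF layout written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        wl = np.asarray(nirs["probe"]["wavelengths"])
        ml_keys = sorted(
            (k for k in data if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        widx = np.array([int(data[k]["wavelengthIndex"][()]) for k in ml_keys])
        sidx = np.array([int(data[k]["sourceIndex"][()]) for k in ml_keys])
        didx = np.array([int(data[k]["detectorIndex"][()]) for k in ml_keys])
        nw = len(wl)
        nc = len(ml_keys) // nw
        if nc * nw != len(ml_keys):
            raise ValueError("measurement list does not factor into wavelengths x channels")
        cube = series.T.reshape(nw, nc, -1)
        sep = np.asarray(
            nirs["probe"].get("sourceDetectorSeparation_mm", np.full(nc, 30.0))
        )
        montage = Montage(
            channel_id=np.arange(1, nc + 1),
            source_id=sidx[:nc],
            detector_id=didx[:nc],
            separation_mm=sep,
        )
        rows = []
        for k in sorted((k for k in nirs if k.startswith("stim")),
                        key=lambda k: int(k[len("stim"):])):
            st = nirs[k]
            onset, dur, _ = np.asarray(st["data"])[0]
            name = st["name"][()]
            cond = st["condition"][()] if "condition" in st else b""
            rows.append(
                {
                    "clip_id": name.decode() if isinstance(name, bytes) else str(name),
                    "onset_s": float(onset),
                    "offset_s": float(onset + dur),
                    "condition": cond.decode() if isinstance(cond, bytes) else str(cond),
                }
            )
        fs = 1.0 / float(np.diff(time)[0])
    return RawRecording(
        intensity=cube,
        wavelengths_nm=wl,
        fs=fs,
        montage=montage,
        events=pd.DataFrame(rows),
    )


def read_recording(path: str, dialect: str = "long-csv", events: pd.DataFrame | None = None,
                   montage: Montage | None = None) -> RawRecording:
    """Dispatch recording input by dialect: ``"long-csv"`` or ``"snirf"``."""
    if dialect == "long-csv":
        if events is None:
            raise ValueError("long-csv dialect requires an events table")
        return read_recording_csv(path, events, montage)
    if dialect == "snirf":
        return read_snirf(path)
    raise ValueError(f"unknown dialect {dialect!r}")
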