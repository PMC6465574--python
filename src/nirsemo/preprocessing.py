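"""Band-pass filtering, baseline correction, epoching and feature extraction.

The decoding features are spatial patterns: for each film clip the last
30 s of the hemodynamic response are cut into three non-overlapping 10-s
windows, and each window is reduced to the per-channel time mean,
yielding one 24-dimensional vector per window and chromophore.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .optics import HemoSeries, RawRecording

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSample",
    "SampleWindow",
    "validate_events",
    "bandpass",
    "bandpass_intensity",
    "baseline_correct",
    "extract_samples",
    "build_features",
    "features_to_frame",
]

CHROMOPHORES = ("HbO", "HbR")


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def validate_events(
    events: pd.DataFrame, min_duration_s: float = 30.0, min_lead_s: float = 10.0
) -> pd.DataFrame:
    """Check the event table invariants and return it sorted by onset.

    Clips must last at least ``min_duration_s``, start at least
    ``min_lead_s`` after recording start, and must not overlap.
    """
    ev = events.sort_values("onset_s").reset_index(drop=True)
    dur = ev["offset_s"] - ev["onset_s"]
    if (dur < min_duration_s).any():
        bad = ev.loc[dur < min_duration_s, "clip_id"].tolist()
        raise ValueError(f"clips shorter than {min_duration_s} s: {bad}")
    if (ev["onset_s"] < min_lead_s).any():
        raise ValueError(f"first clip onset must be >= {min_lead_s} s after start")
    if (ev["onset_s"].values[1:] < ev["offset_s"].values[:-1]).any():
        raise ValueError("events overlap")
    return ev


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _design_bandpass(low_hz: float, high_hz: float, fs: float, order: int = 4):
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for sampling rate {fs} Hz"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(
    x: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.2,
    fs: float = 50.0,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    The default 0.01-0.2 Hz band keeps slow hemodynamics while rejecting
    cardiac (~1.2 Hz) and respiratory (~0.25 Hz) oscillations; Mayer waves
    (~0.1 Hz) fall inside the band and are not removed by filtering alone.
    """
    sos = _design_bandpass(low_hz, high_hz, fs, order)
    x = np.asarray(x, dtype=float)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[axis] <= padlen:
        raise ValueError(
            f"series too short for filtering: length {x.shape[axis]} <= pad {padlen}"
        )
    return signal.sosfiltfilt(sos, x, axis=axis)


def bandpass_intensity(
    raw: RawRecording,
    low_hz: float = 0.01,
    high_hz: float = 0.2,
    order: int = 4,
) -> RawRecording:
    """Band-pass the raw intensity fluctuations, keeping the mean level.

    The filter is applied to the fluctuation about each channel's mean
    intensity and the mean is restored afterwards, so intensities stay
    positive and the subsequent ln(I_ref/I) conversion is defined.  For
    the small fractional fluctuations typical of fNIRS this is equivalent,
    to first order, to band-pass filtering the optical density itself.
    """
    mean = raw.intensity.mean(axis=2, keepdims=True)
    filt = bandpass(raw.intensity - mean, low_hz, high_hz, raw.fs, order, axis=2)
    return RawRecording(
        intensity=filt + mean,
        wavelengths_nm=raw.wavelengths_nm,
        fs=raw.fs,
        montage=raw.montage,
        events=raw.events,
    )


# ---------------------------------------------------------------------------
# Baseline correction and epoching
# ---------------------------------------------------------------------------

def baseline_correct(
    hemo: HemoSeries, events: pd.DataFrame, window_s: float = 10.0
) -> HemoSeries:
    """Subtract each clip's pre-stimulus mean from its response.

    For every clip, the per-channel mean over [onset - window_s, onset) is
    subtracted from the samples in [onset, offset).  Samples outside clips
    are left untouched.
    """
    out = hemo.copy()
    fs = hemo.fs
    for _, ev in events.iterrows():
        on = int(round(ev["onset_s"] * fs))
        off = int(round(ev["offset_s"] * fs))
        base_start = on - int(round(window_s * fs))
        if base_start < 0:
            raise ValueError(
                f"clip {ev['clip_id']}: insufficient pre-stimulus data for a "
                f"{window_s}-s baseline"
            )
        for arr in (out.hbo, out.hbr):
            base = arr[:, base_start:on].mean(axis=1, keepdims=True)
            arr[:, on:off] -= base
    return out


@dataclass(frozen=True)
class SampleWindow:
    """One 10-s epoch of a clip: per-chromophore (n_channels, n_samples) data."""

    clip_id: object
    condition: str
    sample_index: int  # 1..3, earliest to latest
    hbo: np.ndarray
    hbr: np.ndarray


def extract_samples(
    hemo: HemoSeries,
    events: pd.DataFrame,
    window_s: float = 10.0,
    n_windows: int = 3,
) -> list[SampleWindow]:
    """Cut the last ``n_windows * window_s`` seconds of each clip into
    non-overlapping windows.

    With the defaults, windows tile [offset-30, offset) as
    [offset-30, offset-20), [offset-20, offset-10), [offset-10, offset);
    at 50 Hz each holds exactly 500 time points.  Clips shorter than the
    extracted span are an error — no partial windows are produced.
    """
    fs = hemo.fs
    wlen = int(round(window_s * fs))
    span = n_windows * window_s
    out: list[SampleWindow] = []
    for _, ev in events.iterrows():
        dur = ev["offset_s"] - ev["onset_s"]
        if dur < span:
            raise ValueError(
                f"clip {ev['clip_id']} lasts {dur:g} s < required {span:g} s"
            )
        off = int(round(ev["offset_s"] * fs))
        start0 = off - n_windows * wlen
        for k in range(n_windows):
            sl = slice(start0 + k * wlen, start0 + (k + 1) * wlen)
            out.append(
                SampleWindow(
                    clip_id=ev["clip_id"],
                    condition=str(ev["condition"]),
                    sample_index=k + 1,
                    hbo=hemo.hbo[:, sl],
                    hbr=hemo.hbr[:, sl],
                )
            )
    logger.debug("extracted %d windows from %d clips", len(out), len(events))
    return out


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSample:
    """One spatial feature vector: per-channel mean concentration change (uM)."""

    participant_id: object
    clip_id: object
    sample_index: int
    chromophore: str
    vector: np.ndarray
    category: str


def build_features(
    windows: list[SampleWindow],
    participant_id: object,
    n_channels: int = 24,
) -> list[FeatureSample]:
    """Reduce each window to its per-channel time mean, per chromophore.

    Each window yields two samples (HbO and HbR), whose vectors have one
    entry per channel — 24 dimensions for the standard frontal montage.
    """
    feats: list[FeatureSample] = []
    for w in windows:
        if w.hbo.shape[0] != n_channels:
            raise ValueError(
                f"window for clip {w.clip_id} has {w.hbo.shape[0]} channels, "
                f"expected {n_channels}"
            )
        for chrom, arr in (("HbO", w.hbo), ("HbR", w.hbr)):
            feats.append(
                FeatureSample(
                    participant_id=participant_id,
                    clip_id=w.clip_id,
                    sample_index=w.sample_index,
                    chromophore=chrom,
                    vector=arr.mean(axis=1),
                    category=w.condition,
                )
            )
    return feats


def features_to_frame(features: list[FeatureSample]) -> pd.DataFrame:
    """Tabulate feature samples: metadata columns + ch_1..ch_N."""
    if not features:
        return pd.DataFrame()
    n = len(features[0].vector)
    rows = []
    for f in features:
        row = {
            "participant_id": f.participant_id,
            "clip_id": f.clip_id,
            "sample_index": f.sample_index,
            "chromophore": f.chromophore,
            "category": f.category,
        }
        row.update({f"ch_{i + 1}": v for i, v in enumerate(f.vector)})
        rows.append(row)
    return pd.DataFrame(rows)
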