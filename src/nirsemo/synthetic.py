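"""Synthetic study generator: raw fNIRS recordings and rating matrices.

The generator emulates the film-clip positive-emotion study design so
that every analysis stage can be exercised without any recorded data:

* 13 participants, 37 film clips (30 positive — 10 emotions x 3 clips —
  6 negative, 1 neutral), clip durations 30-129 s with mean ~70 s,
  inter-trial rest of at least 45 s;
* 24-channel frontal montage sampled at 50 Hz at three wavelengths
  (785/808/850 nm), intensities produced by the *forward* modified
  Beer-Lambert law from ground-truth concentration changes, so the
  package's inverse recovers the truth exactly in the noise-free case;
* cluster-specific spatial activation patterns (encouragement: medial
  HbO increase; playfulness: global HbR decrease; harmony: left-lateral
  pattern; negative: right-lateral pattern) — plausibility fixtures,
  configurable, not measured quantities;
* physiological noise: cardiac (~1.2 Hz), respiratory (~0.25 Hz) and
  Mayer-wave (~0.1 Hz) oscillations with per-channel frequency/phase
  jitter, a 1/f-like drift, white noise, and multiplicative measurement
  noise on the intensities;
* Likert rating matrices drawn from a latent Gaussian whose target
  correlation structure is the published 14-item rating correlation
  matrix (projected to the nearest positive-definite matrix), with a
  per-clip target-emotion elevation, discretised to the 1-7 scale.

All generators are pure functions of (design, seed): the same inputs
reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import (
    ALL_ITEMS,
    DEFAULT_CLUSTERS,
    POSITIVE_ITEMS,
    ClusterDefinition,
    RatingMatrix,
)
from .optics import (
    DEFAULT_EXTINCTION,
    ExtinctionTable,
    HemoSeries,
    Montage,
    RawRecording,
    default_montage,
    forward_mbll,
)

__all__ = [
    "RATING_CORRELATION_TARGET",
    "NoiseModel",
    "RatingModel",
    "SimDesign",
    "GroundTruth",
    "nearest_positive_definite",
    "default_patterns",
    "gen_ratings",
    "gen_recording",
    "gen_cohort",
    "gen_null_cohort",
]

# Published pairwise Pearson correlations between the 14 rating items
# (cross-participant mean ratings over the 30 positive clips); used as the
# rating generator's target correlation structure.  Item order matches
# behavior.ALL_ITEMS.
_T1 = np.ones((14, 14))
_T1_LOWER = [
    [],
    [-0.48],
    [-0.05, 0.56],
    [0.12, 0.44, 0.94],
    [0.27, 0.47, 0.87, 0.94],
    [0.81, -0.05, 0.36, 0.51, 0.66],
    [0.88, -0.23, 0.31, 0.48, 0.60, 0.92],
    [0.14, -0.14, 0.51, 0.59, 0.41, 0.26, 0.38],
    [0.03, 0.62, 0.85, 0.83, 0.89, 0.45, 0.41, 0.34],
    [-0.20, 0.30, 0.50, 0.46, 0.30, 0.11, 0.06, 0.45, 0.37],
    [0.62, -0.02, 0.09, 0.19, 0.42, 0.56, 0.58, -0.11, 0.31, -0.56],
    [0.63, 0.07, 0.68, 0.79, 0.85, 0.85, 0.86, 0.50, 0.68, 0.31, 0.42],
    [0.43, 0.02, 0.33, 0.41, 0.53, 0.51, 0.53, -0.02, 0.48, -0.02, 0.50, 0.58],
    [0.69, 0.06, 0.59, 0.71, 0.81, 0.92, 0.89, 0.41, 0.64, 0.20, 0.53, 0.94, 0.58],
]
for _i, _row in enumerate(_T1_LOWER):
    for _j, _v in enumerate(_row):
        _T1[_i, _j] = _T1[_j, _i] = _v
RATING_CORRELATION_TARGET = pd.DataFrame(_T1, index=list(ALL_ITEMS), columns=list(ALL_ITEMS))


def nearest_positive_definite(corr: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest PD correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal renormalised
    to one (Higham-style alternating step, one pass — adequate for
    mildly indefinite empirical correlation tables).
    """
    a = np.asarray(corr, dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("correlation target must be symmetric")
    w, v = np.linalg.eigh(a)
    w = np.clip(w, eig_floor, None)
    b = (v * w) @ v.T
    d = np.sqrt(np.diag(b))
    b = b / np.outer(d, d)
    return (b + b.T) / 2


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Physiological + instrumental noise amplitudes (HbO scale, uM).

    HbR components reuse the same structure scaled by ``hbr_scale``.
    Sinusoid amplitudes are peak values; frequencies get per-channel
    Gaussian jitter (``*_jitter_hz``) and random phases.
    """

    cardiac_amp: float = 0.15
    cardiac_hz: float = 1.2
    cardiac_jitter_hz: float = 0.05
    resp_amp: float = 0.10
    resp_hz: float = 0.25
    resp_jitter_hz: float = 0.02
    mayer_amp: float = 0.12
    mayer_hz: float = 0.10
    mayer_jitter_hz: float = 0.01
    drift_sd: float = 0.20          # 1/f-like random-walk drift, uM
    white_sd: float = 0.05          # per-sample white noise, uM
    hbr_scale: float = 0.4
    measurement_sd: float = 0.005   # multiplicative intensity noise


@dataclass(frozen=True)
class RatingModel:
    """Latent-Gaussian rating model parameters (latent-SD units)."""

    target_shift: float = 2.0        # elevation of a clip's target emotion
    cluster_shift: float = 1.5       # elevation of the target's cluster-mates
    participant_noise_sd: float = 0.5
    negative_shift: float = -1.5     # positive items on negative clips
    neutral_shift: float = -1.0


@dataclass(frozen=True)
class SimDesign:
    """Study conditions for the synthetic cohort."""

    n_participants: int = 13
    clips_per_emotion: int = 3
    n_negative: int = 6
    n_neutral: int = 1
    fs: float = 50.0
    n_channels: int = 24
    duration_range_s: tuple = (30.0, 129.0)
    duration_beta: tuple = (2.0, 2.95)  # Beta shape giving mean ~70 s on the range
    rest_s: float = 45.0
    rest_jitter_s: float = 15.0
    lead_in_s: float = 60.0
    tail_s: float = 30.0
    amp_hbo: float = 0.4            # uM, peak cluster-pattern amplitude
    amp_hbr: float = 0.2
    clip_amp_range: tuple = (0.6, 1.4)
    participant_scale_range: tuple = (0.7, 1.3)
    ramp_s: float = 5.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    rating: RatingModel = field(default_factory=RatingModel)
    clusters: ClusterDefinition = field(default_factory=lambda: DEFAULT_CLUSTERS)
    separation_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.duration_range_s[0] < 30.0:
            raise ValueError("clip durations must be at least 30 s")
        if self.amp_hbo < 0 or self.amp_hbr < 0:
            raise ValueError("effect amplitudes must be nonnegative")

    @property
    def n_positive(self) -> int:
        return self.clips_per_emotion * len(POSITIVE_ITEMS)

    @property
    def n_clips(self) -> int:
        return self.n_positive + self.n_negative + self.n_neutral

    def montage(self) -> Montage:
        return default_montage(self.n_channels, self.separation_mm)

    def extinction(self) -> ExtinctionTable:
        return DEFAULT_EXTINCTION

    def clip_table(self) -> pd.DataFrame:
        """Clip metadata: clip_id, condition, target_emotion, pattern key."""
        rows = []
        for i in range(self.n_positive):
            emotion = POSITIVE_ITEMS[i // self.clips_per_emotion]
            rows.append(
                {
                    "clip_id": f"pos{i + 1:02d}",
                    "condition": "positive",
                    "target_emotion": emotion,
                    "pattern": self.clusters.cluster_of(emotion),
                }
            )
        for i in range(self.n_negative):
            rows.append(
                {
                    "clip_id": f"neg{i + 1}",
                    "condition": "negative",
                    "target_emotion": "",
                    "pattern": "negative",
                }
            )
        for i in range(self.n_neutral):
            rows.append(
                {
                    "clip_id": f"neu{i + 1}",
                    "condition": "neutral",
                    "target_emotion": "",
                    "pattern": "neutral",
                }
            )
        return pd.DataFrame(rows)

    def clip_durations(self, seed: int) -> pd.Series:
        """Stimulus durations (s), shared across participants for a seed."""
        rng = np.random.default_rng([int(seed), 11])
        lo, hi = self.duration_range_s
        a, b = self.duration_beta
        clips = self.clip_table()
        dur = lo + (hi - lo) * rng.beta(a, b, size=len(clips))
        return pd.Series(np.round(dur, 1), index=clips["clip_id"])


def default_patterns(n_channels: int = 24) -> dict:
    """Cluster-specific spatial response patterns (unit peak amplitude).

    Channels are taken row-major on a 4 x 6 grid; columns 0-1 are left,
    2-3 medial, 4-5 right.  Values multiply the design's amp_hbo/amp_hbr.
    """
    cols = np.arange(n_channels) % 6
    left = (cols <= 1).astype(float)
    medial = ((cols == 2) | (cols == 3)).astype(float)
    right = (cols >= 4).astype(float)
    ones = np.ones(n_channels)
    return {
        "encouragement": {"hbo": medial + 0.2 * (1 - medial), "hbr": -0.3 * medial},
        "playfulness": {"hbo": 0.3 * ones, "hbr": -1.0 * ones},
        "harmony": {"hbo": 0.8 * left, "hbr": -0.6 * left},
        "negative": {"hbo": 0.8 * right, "hbr": -0.3 * right},
        "neutral": {"hbo": 0.0 * ones, "hbr": 0.0 * ones},
    }


@dataclass
class GroundTruth:
    """What was injected: enough to rebuild the noise-free signal."""

    design: SimDesign
    seed: int
    participant_id: object
    events: pd.DataFrame            # clip_id, onset_s, offset_s, condition
    clip_effects: pd.DataFrame      # clip_id, pattern, amp_factor
    patterns: dict
    participant_scale: float
    n_times: int

    def clean_concentration(self) -> HemoSeries:
        """Noise-free ground-truth concentration changes (uM)."""
        d = self.design
        nch = d.n_channels
        hbo = np.zeros((nch, self.n_times))
        hbr = np.zeros((nch, self.n_times))
        eff = self.clip_effects.set_index("clip_id")
        for _, ev in self.events.iterrows():
            row = eff.loc[ev["clip_id"]]
            pat = self.patterns[row["pattern"]]
            box = _ramped_boxcar(
                self.n_times, ev["onset_s"], ev["offset_s"], d.fs, d.ramp_s
            )
            scale = row["amp_factor"] * self.participant_scale
            hbo += np.outer(pat["hbo"] * d.amp_hbo * scale, box)
            hbr += np.outer(pat["hbr"] * d.amp_hbr * scale, box)
        return HemoSeries(
            hbo=hbo, hbr=hbr, fs=d.fs, channel_id=d.montage().channel_id
        )


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

def _latent_clip_means(design: SimDesign, corr_pd: np.ndarray, rng) -> np.ndarray:
    """Per-clip latent item means: correlated base + condition shifts."""
    clips = design.clip_table()
    rm = design.rating
    chol = np.linalg.cholesky(corr_pd)
    base = rng.standard_normal((len(clips), len(ALL_ITEMS))) @ chol.T
    idx = {item: i for i, item in enumerate(ALL_ITEMS)}
    for c, row in clips.iterrows():
        if row["condition"] == "positive":
            target = row["target_emotion"]
            base[c, idx[target]] += rm.target_shift
            # a clip elicits its whole cluster: mates get a smaller elevation
            for mate in design.clusters.items_of(design.clusters.cluster_of(target)):
                if mate != target:
                    base[c, idx[mate]] += rm.cluster_shift
        elif row["condition"] == "negative":
            for item in POSITIVE_ITEMS:
                base[c, idx[item]] += rm.negative_shift
            base[c, idx["valence"]] += 2 * rm.negative_shift
        else:
            base[c, :] += rm.neutral_shift
    return base


def gen_ratings(
    design: SimDesign, seed: int, target_corr: pd.DataFrame | None = None
) -> tuple[RatingMatrix, dict]:
    """Simulate the participants x clips x items Likert rating tensor.

    Latent Gaussian clip profiles follow the (PD-projected) target
    correlation; each participant observes the clip profile plus
    independent Gaussian noise; latents map to 1-7 by equal-probability
    thresholds of the marginal latent distribution.  Returns the rating
    matrix and a ground-truth dict (latent clip means, thresholds).
    """
    if target_corr is None:
        target_corr = RATING_CORRELATION_TARGET
    corr_pd = nearest_positive_definite(target_corr.to_numpy())
    rng = np.random.default_rng([int(seed), 21])
    clips = design.clip_table()
    mu = _latent_clip_means(design, corr_pd, rng)
    sd_p = design.rating.participant_noise_sd
    latent = (
        mu[None, :, :]
        + sd_p * rng.standard_normal((design.n_participants, len(clips), len(ALL_ITEMS)))
    )
    # equal-probability bin edges of the marginal latent N(0, 1 + sd_p^2)
    from scipy.stats import norm

    marg_sd = np.sqrt(1.0 + sd_p**2)
    edges = norm.ppf(np.arange(1, 7) / 7.0, scale=marg_sd)
    values = 1 + np.digitize(latent, edges)
    ratings = RatingMatrix(
        values=values.astype(float),
        participants=[f"sub{p + 1:02d}" for p in range(design.n_participants)],
        clips=clips,
        items=ALL_ITEMS,
    )
    truth = {"latent_clip_means": mu, "thresholds": edges, "corr_target_pd": corr_pd}
    return ratings, truth


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def _ramped_boxcar(n_times, onset_s, offset_s, fs, ramp_s) -> np.ndarray:
    """Unit boxcar over [onset, offset) with linear onset/offset ramps."""
    t = np.arange(n_times) / fs
    up = np.clip((t - onset_s) / max(ramp_s, 1e-9), 0.0, 1.0)
    down = np.clip((offset_s - t) / max(ramp_s, 1e-9), 0.0, 1.0)
    return np.minimum(up, down) * ((t >= onset_s) & (t < offset_s))


def _schedule(design: SimDesign, durations: pd.Series, rng) -> pd.DataFrame:
    """Event table: neutral first, negatives, then positives (shuffled)."""
    clips = design.clip_table()
    neu = clips[clips["condition"] == "neutral"]["clip_id"].tolist()
    neg = clips[clips["condition"] == "negative"]["clip_id"].tolist()
    pos = clips[clips["condition"] == "positive"]["clip_id"].tolist()
    order = neu + list(rng.permutation(neg)) + list(rng.permutation(pos))
    cond = clips.set_index("clip_id")["condition"]
    rows = []
    t = design.lead_in_s
    for cid in order:
        dur = float(durations[cid])
        rows.append(
            {"clip_id": cid, "onset_s": t, "offset_s": t + dur, "condition": cond[cid]}
        )
        t += dur + design.rest_s + float(rng.uniform(0, design.rest_jitter_s))
    return pd.DataFrame(rows)


def _physio_noise(nm: NoiseModel, n_channels: int, n_times: int, fs: float, rng):
    """One chromophore's worth of structured noise, (n_channels, n_times)."""
    t = np.arange(n_times) / fs
    out = np.zeros((n_channels, n_times))
    for amp, f0, jit in (
        (nm.cardiac_amp, nm.cardiac_hz, nm.cardiac_jitter_hz),
        (nm.resp_amp, nm.resp_hz, nm.resp_jitter_hz),
        (nm.mayer_amp, nm.mayer_hz, nm.mayer_jitter_hz),
    ):
        freqs = f0 + jit * rng.standard_normal(n_channels)
        phases = rng.uniform(0, 2 * np.pi, n_channels)
        amps = amp * rng.uniform(0.8, 1.2, n_channels)
        out += amps[:, None] * np.sin(
            2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
        )
    # 1/f-like drift: normalised random walk per channel
    walk = np.cumsum(rng.standard_normal((n_channels, n_times)), axis=1)
    walk -= walk.mean(axis=1, keepdims=True)
    sd = walk.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    out += nm.drift_sd * walk / sd
    out += nm.white_sd * rng.standard_normal((n_channels, n_times))
    return out


def gen_recording(
    design: SimDesign,
    participant: int,
    seed: int,
    patterns: dict | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Simulate one participant's raw tri-wavelength intensity recording.

    Ground-truth concentration = cluster pattern x ramped boxcar per clip
    (clip- and participant-specific amplitude factors) + physiological
    noise; converted to optical density by the forward MBLL with the
    design's extinction table, then to intensity
    I = I_ref * exp(-dOD) * (1 + measurement noise).
    """
    if patterns is None:
        patterns = default_patterns(design.n_channels)
    durations = design.clip_durations(seed)
    prng = np.random.default_rng([int(seed), 31, int(participant)])
    events = _schedule(design, durations, prng)
    if (events["onset_s"].values[1:] < events["offset_s"].values[:-1]).any():
        raise ValueError("schedule overlaps")
    n_times = int(np.ceil((events["offset_s"].iloc[-1] + design.tail_s) * design.fs))
    montage = design.montage()

    part_scale = float(prng.uniform(*design.participant_scale_range))
    amp_factors = prng.uniform(*design.clip_amp_range, size=len(events))
    clip_effects = pd.DataFrame(
        {
            "clip_id": events["clip_id"].to_numpy(),
            "pattern": design.clip_table()
            .set_index("clip_id")
            .loc[events["clip_id"], "pattern"]
            .to_numpy(),
            "amp_factor": amp_factors,
        }
    )
    truth = GroundTruth(
        design=design,
        seed=seed,
        participant_id=participant,
        events=events,
        clip_effects=clip_effects,
        patterns=patterns,
        participant_scale=part_scale,
        n_times=n_times,
    )

    clean = truth.clean_concentration()
    nm = design.noise
    hbo = clean.hbo + _physio_noise(nm, design.n_channels, n_times, design.fs, prng)
    hbr = clean.hbr + nm.hbr_scale * _physio_noise(
        nm, design.n_channels, n_times, design.fs, prng
    )
    hemo = HemoSeries(hbo=hbo, hbr=hbr, fs=design.fs, channel_id=montage.channel_id)
    od = forward_mbll(hemo, design.extinction(), montage)

    i_ref = prng.uniform(0.5, 2.0, size=(od.od.shape[0], design.n_channels))
    intensity = i_ref[:, :, None] * np.exp(-od.od)
    if nm.measurement_sd > 0:
        intensity *= 1.0 + nm.measurement_sd * prng.standard_normal(intensity.shape)
    if np.any(intensity <= 0):
        raise ValueError("measurement noise drove intensity non-positive")
    raw = RawRecording(
        intensity=intensity,
        wavelengths_nm=design.extinction().wavelengths_nm,
        fs=design.fs,
        montage=montage,
        events=events,
    )
    return raw, truth


def gen_cohort(design: SimDesign, seed: int, patterns: dict | None = None):
    """Lazily yield (participant_id, RawRecording, GroundTruth) per participant."""
    for p in range(design.n_participants):
        raw, truth = gen_recording(design, p, seed, patterns=patterns)
        yield f"sub{p + 1:02d}", raw, truth


def gen_null_cohort(design: SimDesign, seed: int):
    """A cohort with all class-effect amplitudes set to zero.

    Identical to :func:`gen_cohort` except that no cluster pattern is
    injected, so class labels are statistically independent of the
    features — the fixture for chance-level estimation.
    """
    null_design = replace(design, amp_hbo=0.0, amp_hbr=0.0)
    yield from gen_cohort(null_design, seed)
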