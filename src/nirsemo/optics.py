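"""Modified Beer-Lambert law (MBLL) conversions for continuous-wave fNIRS.

A continuous-wave fNIRS channel measures light intensity at several
near-infrared wavelengths.  The change in optical density

    dOD(lambda, t) = ln(I_ref(lambda) / I(lambda, t))

is, under the MBLL, a linear function of the oxy- and deoxy-hemoglobin
concentration changes dC_HbO and dC_HbR (in micromolar):

    dOD(lambda) = (eps_HbO(lambda) * dC_HbO + eps_HbR(lambda) * dC_HbR)
                  * r * DPF(lambda)

where ``eps`` are the wavelength-dependent extinction coefficients
(mm^-1 uM^-1, natural-log convention), ``r`` the source-detector
separation (mm) and ``DPF`` the differential path-length factor that
rescales the geometric distance to the effective photon path length.

With three wavelengths and two chromophores the inversion is an
overdetermined 3x2 linear system per channel and time point, solved here
in the least-squares sense (Moore-Penrose pseudoinverse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Montage",
    "ExtinctionTable",
    "OpticalDensitySeries",
    "HemoSeries",
    "RawRecording",
    "DEFAULT_EXTINCTION",
    "default_montage",
    "compute_delta_od",
    "forward_mbll",
    "invert_mbll",
]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Probe geometry: one row per measurement channel.

    Parameters
    ----------
    channel_id : 1-based channel identifiers (24 for the standard frontal cap).
    source_id, detector_id : probe indices forming each channel.
    separation_mm : source-detector distance r, in millimetres.
    """

    channel_id: np.ndarray
    source_id: np.ndarray
    detector_id: np.ndarray
    separation_mm: np.ndarray

    def __post_init__(self) -> None:
        cid = np.asarray(self.channel_id, dtype=int)
        if len(np.unique(cid)) != len(cid):
            raise ValueError("channel ids must be unique")
        sep = np.asarray(self.separation_mm, dtype=float)
        if np.any(sep <= 0):
            raise ValueError("source-detector separation must be positive")
        object.__setattr__(self, "channel_id", cid)
        object.__setattr__(self, "source_id", np.asarray(self.source_id, dtype=int))
        object.__setattr__(self, "detector_id", np.asarray(self.detector_id, dtype=int))
        object.__setattr__(self, "separation_mm", sep)

    @property
    def n_channels(self) -> int:
        return len(self.channel_id)


def default_montage(n_channels: int = 24, separation_mm: float = 30.0) -> Montage:
    """Frontal cap stand-in: ``n_channels`` channels at a uniform separation.

    The real device pairs 6 sources with 14 detectors; only the separation
    enters the MBLL, so sources/detectors are assigned schematically.
    """
    ch = np.arange(1, n_channels + 1)
    return Montage(
        channel_id=ch,
        source_id=1 + (ch - 1) // 4,
        detector_id=1 + (ch - 1) % 14,
        separation_mm=np.full(n_channels, float(separation_mm)),
    )


@dataclass(frozen=True)
class ExtinctionTable:
    """Per-wavelength extinction coefficients and DPF values.

    ``eps_hbo``/``eps_hbr`` are natural-log specific absorption
    coefficients in mm^-1 uM^-1; ``dpf`` is dimensionless.
    """

    wavelengths_nm: np.ndarray
    eps_hbo: np.ndarray
    eps_hbr: np.ndarray
    dpf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wavelengths_nm", "eps_hbo", "eps_hbr", "dpf"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.wavelengths_nm) == len(self.eps_hbo) == len(self.eps_hbr) == len(self.dpf)):
            raise ValueError("wavelengths, extinction coefficients and DPF must align")
        if np.any(self.eps_hbo <= 0) or np.any(self.eps_hbr <= 0):
            raise ValueError("extinction coefficients must be positive")
        if np.any(self.dpf <= 0):
            raise ValueError("DPF must be positive")

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths_nm)

    @property
    def matrix(self) -> np.ndarray:
        """The (n_wavelengths, 2) matrix [eps_HbO, eps_HbR]."""
        return np.column_stack([self.eps_hbo, self.eps_hbr])

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    @classmethod
    def from_config(cls, path: str) -> "ExtinctionTable":
        """Load a table from a YAML config keyed by wavelength.

        Expected layout::

            wavelengths:
              785: {eps_hbo: 1.695e-4, eps_hbr: 2.538e-4, dpf: 6.1}
              808: {eps_hbo: 1.957e-4, eps_hbr: 1.681e-4, dpf: 6.0}
              850: {eps_hbo: 2.437e-4, eps_hbr: 1.591e-4, dpf: 5.8}
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        wl = sorted(cfg["wavelengths"])
        rows = [cfg["wavelengths"][w] for w in wl]
        return cls(
            wavelengths_nm=np.array(wl, dtype=float),
            eps_hbo=np.array([r["eps_hbo"] for r in rows]),
            eps_hbr=np.array([r["eps_hbr"] for r in rows]),
            dpf=np.array([r["dpf"] for r in rows]),
        )

    def to_config(self, path: str) -> None:
        cfg = {
            "wavelengths": {
                float(w): {
                    "eps_hbo": float(self.eps_hbo[i]),
                    "eps_hbr": float(self.eps_hbr[i]),
                    "dpf": float(self.dpf[i]),
                }
                for i, w in enumerate(self.wavelengths_nm)
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh)


# Tabulated hemoglobin extinction values at 785/808/850 nm (natural-log
# convention, mm^-1 uM^-1) and typical adult-forehead DPFs.  The acquisition
# device's exact calibration is not public; all values are overridable and
# the synthetic generator uses this same table, so round trips are exact.
DEFAULT_EXTINCTION = ExtinctionTable(
    wavelengths_nm=np.array([785.0, 808.0, 850.0]),
    eps_hbo=np.array([1.695e-4, 1.957e-4, 2.437e-4]),
    eps_hbr=np.array([2.538e-4, 1.681e-4, 1.591e-4]),
    dpf=np.array([6.1, 6.0, 5.8]),
)


@dataclass
class OpticalDensitySeries:
    """Change in optical density, shape (n_wavelengths, n_channels, n_times)."""

    od: np.ndarray
    wavelengths_nm: np.ndarray
    fs: float
    channel_id: np.ndarray

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3:
            raise ValueError("od must be (n_wavelengths, n_channels, n_times)")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical density contains non-finite values")

    @property
    def n_times(self) -> int:
        return self.od.shape[2]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_s, channel, wavelength_nm, delta_od."""
        nw, nc, nt = self.od.shape
        t = np.arange(nt) / self.fs
        idx = pd.MultiIndex.from_product(
            [self.wavelengths_nm, self.channel_id, t],
            names=["wavelength_nm", "channel", "time_s"],
        )
        return (
            pd.DataFrame({"delta_od": self.od.ravel()}, index=idx)
            .reset_index()[["time_s", "channel", "wavelength_nm", "delta_od"]]
        )


@dataclass
class HemoSeries:
    """Hemoglobin concentration changes in uM, shape (n_channels, n_times) each."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_id: np.ndarray

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape or self.hbo.ndim != 2:
            raise ValueError("hbo and hbr must share shape (n_channels, n_times)")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValueError("hemoglobin series contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_times(self) -> int:
        return self.hbo.shape[1]

    def chromophore(self, name: str) -> np.ndarray:
        if name == "HbO":
            return self.hbo
        if name == "HbR":
            return self.hbr
        raise KeyError(f"unknown chromophore {name!r}")

    def copy(self) -> "HemoSeries":
        return HemoSeries(self.hbo.copy(), self.hbr.copy(), self.fs, self.channel_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_s, channel, chromophore, conc_um."""
        nc, nt = self.hbo.shape
        t = np.arange(nt) / self.fs
        frames = []
        for name, arr in (("HbO", self.hbo), ("HbR", self.hbr)):
            idx = pd.MultiIndex.from_product(
                [self.channel_id, t], names=["channel", "time_s"]
            )
            df = pd.DataFrame({"conc_um": arr.ravel()}, index=idx).reset_index()
            df["chromophore"] = name
            frames.append(df)
        return pd.concat(frames, ignore_index=True)[
            ["time_s", "channel", "chromophore", "conc_um"]
        ]


@dataclass
class RawRecording:
    """Raw light-intensity time series with events and geometry.

    intensity has shape (n_wavelengths, n_channels, n_times); events is a
    table with columns clip_id, onset_s, offset_s, condition.
    """

    intensity: np.ndarray
    wavelengths_nm: np.ndarray
    fs: float
    montage: Montage
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (n_wavelengths, n_channels, n_times)")
        required = {"clip_id", "onset_s", "offset_s", "condition"}
        if not required.issubset(self.events.columns):
            raise ValueError(f"events table needs columns {sorted(required)}")

    @property
    def n_times(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_delta_od(
    raw: RawRecording, reference_policy: str = "mean", prestim_s: float | None = None
) -> OpticalDensitySeries:
    """Convert intensity to optical-density change dOD = ln(I_ref / I).

    reference_policy
        ``"mean"`` (default): I_ref is the per-channel, per-wavelength mean
        over the whole recording.  ``"prestim"``: mean over the window before
        the first event onset (optionally capped at the last ``prestim_s``
        seconds of that window).

    Raises
    ------
    ValueError
        if any intensity sample is non-positive (names the offending
        wavelength, channel and time index).
    """
    inten = raw.intensity
    if np.any(inten <= 0):
        w, c, t = np.argwhere(inten <= 0)[0]
        raise ValueError(
            "non-positive intensity at wavelength "
            f"{raw.wavelengths_nm[w]:g} nm, channel {raw.montage.channel_id[c]}, "
            f"time index {t}"
        )
    if reference_policy == "mean":
        i_ref = inten.mean(axis=2)
    elif reference_policy == "prestim":
        first_onset = float(raw.events["onset_s"].min())
        stop = int(round(first_onset * raw.fs))
        start = 0
        if prestim_s is not None:
            start = max(0, stop - int(round(prestim_s * raw.fs)))
        if stop - start < 1:
            raise ValueError("no pre-stimulus samples available for reference")
        i_ref = inten[:, :, start:stop].mean(axis=2)
    else:
        raise ValueError(f"unknown reference_policy {reference_policy!r}")
    od = np.log(i_ref[:, :, None] / inten)
    return OpticalDensitySeries(
        od=od,
        wavelengths_nm=raw.wavelengths_nm,
        fs=raw.fs,
        channel_id=raw.montage.channel_id,
    )


def forward_mbll(
    hemo: HemoSeries, ext: ExtinctionTable, montage: Montage
) -> OpticalDensitySeries:
    """Forward MBLL: concentration changes -> optical-density changes."""
    if hemo.n_channels != montage.n_channels or not np.array_equal(
        hemo.channel_id, montage.channel_id
    ):
        raise ValueError("hemo series and montage have mismatched channel sets")
    r = montage.separation_mm  # (n_channels,)
    # od[w, c, t] = (eps_hbo[w] hbo[c,t] + eps_hbr[w] hbr[c,t]) * r[c] * dpf[w]
    od = (
        ext.eps_hbo[:, None, None] * hemo.hbo[None, :, :]
        + ext.eps_hbr[:, None, None] * hemo.hbr[None, :, :]
    ) * r[None, :, None] * ext.dpf[:, None, None]
    return OpticalDensitySeries(
        od=od, wavelengths_nm=ext.wavelengths_nm, fs=hemo.fs, channel_id=hemo.channel_id
    )


_MAX_COND = 1e8


def invert_mbll(
    od: OpticalDensitySeries, ext: ExtinctionTable, montage: Montage
) -> HemoSeries:
    """Inverse MBLL: least-squares (dC_HbO, dC_HbR) per channel and time.

    With three wavelengths the system is overdetermined; the Moore-Penrose
    pseudoinverse of the (n_wavelengths, 2) extinction matrix gives the
    least-squares solution of

        dOD(lambda) / (r * DPF(lambda)) = eps_HbO dC_HbO + eps_HbR dC_HbR.
    """
    if ext.n_wavelengths < 3:
        raise ValueError("inversion requires at least 3 wavelengths")
    if od.od.shape[0] != ext.n_wavelengths:
        raise ValueError("od series and extinction table wavelength counts differ")
    if not np.array_equal(od.channel_id, montage.channel_id):
        raise ValueError("od series and montage have mismatched channel sets")
    if ext.condition_number() > _MAX_COND:
        raise ValueError("extinction matrix is rank deficient (condition number too large)")
    r = montage.separation_mm
    # normalise away pathlength: y[w, c, t]
    y = od.od / (r[None, :, None] * ext.dpf[:, None, None])
    pinv = np.linalg.pinv(ext.matrix)  # (2, n_wavelengths)
    conc = np.einsum("kw,wct->kct", pinv, y)
    return HemoSeries(
        hbo=conc[0], hbr=conc[1], fs=od.fs, channel_id=od.channel_id
    )
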