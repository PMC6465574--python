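"""Channel-wise correlation topographies between hemodynamics and ratings.

For every participant, every channel's hemodynamic response to each of
the 30 positive film clips (mean concentration change over the clip's
extracted 30-s window) is correlated with the clip's emotion score
(cluster scores or valence), giving a 24-channel Pearson-r map per score
and chromophore.  Group topographies average the maps across
participants and test each channel against zero (one-sample t on
Fisher-z transformed r by default), with Benjamini-Hochberg correction
across the 24 channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import bh_fdr
from .preprocessing import FeatureSample

logger = logging.getLogger(__name__)

__all__ = [
    "TopoMap",
    "clip_responses",
    "channel_score_correlation",
    "group_topography",
    "topomap_to_frame",
    "plot_topomap",
]


@dataclass
class TopoMap:
    """Per-channel correlation values for one score and chromophore."""

    values: np.ndarray            # (n_channels,) Pearson r (or mean r)
    chromophore: str
    score_name: str
    channel_id: np.ndarray
    p_adj: np.ndarray | None = None
    significant: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and np.max(np.abs(finite)) > 1 + 1e-9:
            raise ValueError("correlation values must lie in [-1, 1]")
        self.values = v


def clip_responses(
    features: list[FeatureSample], chromophore: str, mode: str = "clip-mean"
) -> pd.DataFrame:
    """Per-clip channel responses from extracted feature samples.

    ``"clip-mean"`` (default) averages a clip's three 10-s sample vectors,
    giving one observation per clip (the mean over the extracted 30 s).
    ``"per-sample"`` keeps each 10-s sample as its own observation
    (index = (clip_id, sample_index)).
    """
    rows = [f for f in features if f.chromophore == chromophore]
    if not rows:
        raise ValueError(f"no {chromophore} samples")
    df = pd.DataFrame(
        [f.vector for f in rows],
        index=pd.MultiIndex.from_tuples(
            [(f.clip_id, f.sample_index) for f in rows],
            names=["clip_id", "sample_index"],
        ),
    )
    if mode == "clip-mean":
        return df.groupby(level="clip_id", sort=True).mean()
    if mode == "per-sample":
        return df
    raise ValueError(f"unknown mode {mode!r}")


def channel_score_correlation(
    responses: pd.DataFrame,
    scores: pd.Series,
    chromophore: str,
    score_name: str,
    channel_id: np.ndarray | None = None,
) -> TopoMap:
    """Pearson r between each channel's per-clip response and the score.

    ``responses`` is clips x channels (align its index with ``scores``,
    typically the 30 positive clips).  A zero-variance channel has no
    defined correlation: NaN is emitted with a warning.
    """
    common = responses.index.intersection(scores.index)
    if len(common) < 3:
        raise ValueError("need at least 3 clips to correlate")
    resp = responses.loc[common].to_numpy(dtype=float)
    s = scores.loc[common].to_numpy(dtype=float)
    if np.std(s) == 0:
        raise ValueError(f"score {score_name!r} has zero variance")
    r = np.empty(resp.shape[1])
    for c in range(resp.shape[1]):
        if np.std(resp[:, c]) == 0:
            warnings.warn(
                f"channel {c + 1}: zero-variance response, correlation undefined",
                RuntimeWarning,
            )
            r[c] = np.nan
        else:
            r[c] = np.corrcoef(resp[:, c], s)[0, 1]
    if channel_id is None:
        channel_id = np.arange(1, resp.shape[1] + 1)
    return TopoMap(values=r, chromophore=chromophore, score_name=score_name,
                   channel_id=np.asarray(channel_id))


def group_topography(
    maps: list[TopoMap], alpha: float = 0.05, fisher_z: bool = True
) -> TopoMap:
    """Across-participant mean correlation map with per-channel inference.

    Each channel's participant r values are tested against zero with a
    one-sample t-test (on Fisher-z transformed values by default, since r
    is bounded and skewed under the alternative); the 24 p-values are
    BH-FDR corrected and thresholded at ``alpha``.
    """
    if not maps:
        raise ValueError("no participant maps")
    ref = maps[0]
    for m in maps[1:]:
        if m.score_name != ref.score_name or m.chromophore != ref.chromophore:
            raise ValueError("maps mix scores or chromophores")
    r = np.vstack([m.values for m in maps])  # participants x channels
    mean_r = np.nanmean(r, axis=0)
    x = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)) if fisher_z else r
    nch = r.shape[1]
    p = np.empty(nch)
    for c in range(nch):
        col = x[:, c][np.isfinite(x[:, c])]
        if len(col) < 2 or np.std(col, ddof=1) == 0:
            p[c] = 1.0 if not len(col) or np.allclose(col.mean(), 0) else 0.0
        else:
            p[c] = stats.ttest_1samp(col, 0.0).pvalue
    p_adj = bh_fdr(p)
    return TopoMap(
        values=mean_r,
        chromophore=ref.chromophore,
        score_name=ref.score_name,
        channel_id=ref.channel_id,
        p_adj=p_adj,
        significant=p_adj < alpha,
    )


def topomap_to_frame(tm: TopoMap) -> pd.DataFrame:
    """Export a map as (channel, value, p_adj, significant) rows."""
    df = pd.DataFrame({"channel": tm.channel_id, "value": tm.values})
    df["chromophore"] = tm.chromophore
    df["score"] = tm.score_name
    if tm.p_adj is not None:
        df["p_adj"] = tm.p_adj
        df["significant"] = tm.significant
    return df


def plot_topomap(tm: TopoMap, ax=None, grid_shape: tuple = (4, 6)):
    """Simple channel-grid rendering of a topography (no anatomy).

    Channels are laid out row-major on a ``grid_shape`` grid and coloured
    by correlation value; significant channels (if flagged) are outlined.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    grid = np.full(grid_shape, np.nan)
    for i, v in enumerate(tm.values[: grid_shape[0] * grid_shape[1]]):
        grid[np.unravel_index(i, grid_shape)] = v
    im = ax.imshow(grid, cmap="RdBu_r", vmin=-1, vmax=1)
    for i, ch in enumerate(tm.channel_id[: grid.size]):
        rr, cc = np.unravel_index(i, grid_shape)
        ax.text(cc, rr, str(ch), ha="center", va="center", fontsize=7)
        if tm.significant is not None and tm.significant[i]:
            ax.add_patch(
                plt.Rectangle((cc - 0.5, rr - 0.5), 1, 1, fill=False, lw=2, ec="k")
            )
    ax.set_title(f"{tm.score_name} ({tm.chromophore})")
    ax.set_xticks([])
    ax.set_yticks([])
    plt.colorbar(im, ax=ax, label="Pearson r")
    return ax
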