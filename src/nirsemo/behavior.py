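"""Subjective-rating analytics for the film-clip emotion study.

Participants rate every film clip on 14 seven-point Likert items: the 10
positive emotions (amusement, awe, gratitude, hope, inspiration,
interest, joy, love, pride, serenity) plus arousal, valence, familiarity
and liking.  This module provides

* inter-rater reliability per item (two-way random-effects ICC),
* manipulation checks (one-way repeated-measures ANOVA over the 10
  positive items within each target-emotion clip group, with paired
  post hoc t-tests under Benjamini-Hochberg FDR correction),
* the pairwise Pearson correlation structure of the items across the 30
  positive clips (cross-participant mean ratings),
* nonmetric multidimensional scaling of the 10 positive emotions with
  Kruskal's Stress-1,
* cluster scores (per-clip mean of a cluster's member-item ratings) and
  top-k stimulus selection for the balanced decoding contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "POSITIVE_ITEMS",
    "EXTRA_ITEMS",
    "ALL_ITEMS",
    "DEFAULT_CLUSTERS",
    "ClusterDefinition",
    "RatingMatrix",
    "MdsSolution",
    "icc_per_item",
    "icc2k",
    "rm_anova_1way",
    "manipulation_check",
    "bh_fdr",
    "rating_correlations",
    "mds_embed",
    "cluster_scores",
    "select_top_clips",
    "suggest_clusters",
]

POSITIVE_ITEMS = (
    "amusement",
    "awe",
    "gratitude",
    "hope",
    "inspiration",
    "interest",
    "joy",
    "love",
    "pride",
    "serenity",
)
EXTRA_ITEMS = ("arousal", "valence", "familiarity", "liking")
ALL_ITEMS = POSITIVE_ITEMS + EXTRA_ITEMS


@dataclass(frozen=True)
class ClusterDefinition:
    """Partition of the 10 positive-emotion items into named clusters."""

    mapping: dict = field(
        default_factory=lambda: dict(DEFAULT_CLUSTERS.mapping)
    )

    def __post_init__(self) -> None:
        assigned = [i for items in self.mapping.values() for i in items]
        if sorted(assigned) != sorted(POSITIVE_ITEMS):
            raise ValueError(
                "cluster definition must partition the 10 positive-emotion items"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    def items_of(self, cluster: str) -> tuple[str, ...]:
        return tuple(self.mapping[cluster])

    def cluster_of(self, item: str) -> str:
        for name, items in self.mapping.items():
            if item in items:
                return name
        raise KeyError(item)


# encouragement / playfulness / harmony grouping of the 10 positive emotions
DEFAULT_CLUSTERS = ClusterDefinition(
    mapping={
        "encouragement": ("awe", "gratitude", "hope", "inspiration", "pride"),
        "playfulness": ("amusement", "interest", "joy"),
        "harmony": ("love", "serenity"),
    }
)


@dataclass
class RatingMatrix:
    """Likert ratings: (n_participants, n_clips, n_items), values in [1, 7].

    ``clips`` is a table with columns clip_id, condition
    ('positive'/'negative'/'neutral') and target_emotion (a positive item
    name, or '' for control clips).
    """

    values: np.ndarray
    participants: list
    clips: pd.DataFrame
    items: tuple = ALL_ITEMS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        np_, nc, ni = self.values.shape
        if ni != len(self.items):
            raise ValueError("item axis does not match item names")
        if nc != len(self.clips):
            raise ValueError("clip axis does not match clip table")
        if np.nanmin(self.values) < 1 or np.nanmax(self.values) > 7:
            raise ValueError("Likert values must lie in [1, 7]")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    def item_index(self, item: str) -> int:
        return self.items.index(item)

    def item_table(self, item: str) -> pd.DataFrame:
        """(n_clips, n_participants) table of one item's ratings."""
        return pd.DataFrame(
            self.values[:, :, self.item_index(item)].T,
            index=self.clips["clip_id"],
            columns=self.participants,
        )

    def clip_means(self, condition: str | None = None) -> pd.DataFrame:
        """Cross-participant mean ratings: clips x items."""
        df = pd.DataFrame(
            self.values.mean(axis=0),
            index=self.clips["clip_id"],
            columns=list(self.items),
        )
        if condition is not None:
            df = df.loc[self.clips.loc[self.clips["condition"] == condition, "clip_id"]]
        return df

    def to_frame(self) -> pd.DataFrame:
        """Long format: participant, clip, item, value."""
        np_, nc, ni = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.participants, self.clips["clip_id"], self.items],
            names=["participant", "clip", "item"],
        )
        return pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

def icc2k(table: np.ndarray) -> float:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    ``table`` is (n_targets, n_raters); here targets are film clips and
    raters are participants.  Computed from the two-way ANOVA mean squares:

        ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    with MSR the between-target, MSC the between-rater and MSE the
    residual mean square.  A zero between-target variance makes the
    coefficient degenerate; NaN is returned with a warning.
    """
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 targets and 2 raters")
    grand = x.mean()
    row = x.mean(axis=1)
    col = x.mean(axis=0)
    msr = k * np.sum((row - grand) ** 2) / (n - 1)
    msc = n * np.sum((col - grand) ** 2) / (k - 1)
    mse = np.sum((x - row[:, None] - col[None, :] + grand) ** 2) / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    if denom <= np.finfo(float).eps * max(1.0, abs(msr)):
        warnings.warn("degenerate ICC: no between-clip variance", RuntimeWarning)
        return float("nan")
    return float((msr - mse) / denom)


def icc_per_item(ratings: RatingMatrix, item: str, variant: str = "icc2k") -> float:
    """Inter-rater reliability of one item across all clips.

    ``variant`` selects the ICC form: ``"icc2k"`` (default, average
    measures), ``"icc21"`` (single measures) or ``"icc3k"`` (consistency,
    average measures).
    """
    x = ratings.item_table(item).to_numpy()
    if variant == "icc2k":
        return icc2k(x)
    n, k = x.shape
    grand = x.mean()
    row = x.mean(axis=1)
    col = x.mean(axis=0)
    msr = k * np.sum((row - grand) ** 2) / (n - 1)
    msc = n * np.sum((col - grand) ** 2) / (k - 1)
    mse = np.sum((x - row[:, None] - col[None, :] + grand) ** 2) / ((n - 1) * (k - 1))
    if variant == "icc21":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif variant == "icc3k":
        denom = msr
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    if denom <= np.finfo(float).eps * max(1.0, abs(msr)):
        warnings.warn("degenerate ICC: no between-clip variance", RuntimeWarning)
        return float("nan")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# Manipulation check
# ---------------------------------------------------------------------------

def rm_anova_1way(data: np.ndarray, gg_correction: bool = False):
    """One-way repeated-measures ANOVA on (n_subjects, n_conditions) data.

    Returns (F, df1, df2, p).  With ``gg_correction`` the degrees of
    freedom are multiplied by the Greenhouse-Geisser epsilon estimated
    from the condition covariance matrix.
    """
    x = np.asarray(data, dtype=float)
    ns, nc = x.shape
    if nc < 2 or ns < 2:
        raise ValueError("rmANOVA needs >=2 conditions and >=2 subjects")
    grand = x.mean()
    cond = x.mean(axis=0)
    subj = x.mean(axis=1)
    ss_cond = ns * np.sum((cond - grand) ** 2)
    ss_err = np.sum((x - cond[None, :] - subj[:, None] + grand) ** 2)
    df1, df2 = nc - 1, (nc - 1) * (ns - 1)
    if ss_err == 0:
        warnings.warn("degenerate rmANOVA: zero residual variance", RuntimeWarning)
        return float("inf"), df1, df2, 0.0
    f = (ss_cond / df1) / (ss_err / df2)
    if gg_correction:
        s = np.cov(x, rowvar=False)
        p = s.shape[0]
        dbar = np.diag(s).mean()
        sbar = s.mean()
        eps = (p * (dbar - sbar)) ** 2 / (
            (p - 1)
            * (np.sum(s**2) - 2 * p * np.sum(s.mean(axis=1) ** 2) + p**2 * sbar**2)
        )
        eps = min(1.0, max(1.0 / (p - 1), eps))
        df1, df2 = df1 * eps, df2 * eps
    pval = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, pval


@dataclass
class ManipulationCheck:
    """Result of one target-emotion check over its clip group."""

    target: str
    f: float
    df: tuple
    p: float
    item_means: pd.Series
    posthoc: pd.DataFrame  # item, t, p_raw, p_adj, category


def manipulation_check(
    ratings: RatingMatrix,
    target_emotion: str,
    alpha: float = 0.05,
    gg_correction: bool = False,
) -> ManipulationCheck:
    """Did clips designated to elicit ``target_emotion`` do so?

    For the clip group targeting the emotion, each participant's ratings
    are averaged over the group's clips, giving a subjects x 10-items
    table.  A one-way rmANOVA tests for any item differences; paired
    t-tests compare the target item with each of the other nine, with
    Benjamini-Hochberg correction over those nine p-values.  Items are
    categorised as 'target', 'lower' (significantly below the target),
    'higher', or 'not-different'.
    """
    if target_emotion not in POSITIVE_ITEMS:
        raise ValueError(f"{target_emotion!r} is not a positive-emotion item")
    mask = (ratings.clips["target_emotion"] == target_emotion).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"no clips target {target_emotion!r}")
    cols = [ratings.item_index(i) for i in POSITIVE_ITEMS]
    # subjects x items, averaged over the target's clips
    data = ratings.values[:, mask][:, :, cols].mean(axis=1)
    f, df1, df2, p = rm_anova_1way(data, gg_correction=gg_correction)

    ti = POSITIVE_ITEMS.index(target_emotion)
    others = [i for i in range(len(POSITIVE_ITEMS)) if i != ti]
    tvals, pvals = [], []
    for j in others:
        diff = data[:, ti] - data[:, j]
        if np.allclose(diff.std(ddof=1), 0):
            warnings.warn(
                f"degenerate post hoc: zero-variance contrast "
                f"{target_emotion} vs {POSITIVE_ITEMS[j]}",
                RuntimeWarning,
            )
            t, pr = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
        else:
            t, pr = stats.ttest_rel(data[:, ti], data[:, j])
        tvals.append(float(t))
        pvals.append(float(pr))
    p_adj = bh_fdr(np.array(pvals))

    means = data.mean(axis=0)
    cats = []
    for idx, j in enumerate(others):
        if p_adj[idx] < alpha:
            cats.append("lower" if means[j] < means[ti] else "higher")
        else:
            cats.append("not-different")
    posthoc = pd.DataFrame(
        {
            "item": [POSITIVE_ITEMS[j] for j in others],
            "t": tvals,
            "p_raw": pvals,
            "p_adj": p_adj,
            "category": cats,
        }
    )
    return ManipulationCheck(
        target=target_emotion,
        f=f,
        df=(df1, df2),
        p=p,
        item_means=pd.Series(means, index=list(POSITIVE_ITEMS)),
        posthoc=posthoc,
    )


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Correlation structure and MDS
# ---------------------------------------------------------------------------

def rating_correlations(
    ratings: RatingMatrix,
    items: tuple | None = None,
    condition: str = "positive",
):
    """Pairwise Pearson correlations of cross-participant mean ratings.

    Correlations are computed across the clips of ``condition`` (the 30
    positive clips by default).  Returns (r, p, stars) DataFrames; stars
    are '' / '*' (p<0.05) / '**' (p<0.01), two-sided.
    """
    items = tuple(items) if items is not None else ratings.items
    means = ratings.clip_means(condition)[list(items)]
    n = len(means)
    if n < 3:
        raise ValueError("need at least 3 clips for correlations")
    r = means.corr(method="pearson")
    rv = r.to_numpy(copy=True)
    np.fill_diagonal(rv, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / np.clip(1 - rv**2, 1e-300, None))
    pmat = 2 * stats.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(pmat, 0.0)
    p = pd.DataFrame(pmat, index=r.index, columns=r.columns)
    stars = p.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))
    for i in range(len(items)):
        stars.iloc[i, i] = ""
    return r, p, stars


@dataclass
class MdsSolution:
    """Low-dimensional embedding with its Kruskal Stress-1."""

    coords: pd.DataFrame  # items x dims
    stress1: float

    def distances(self) -> np.ndarray:
        x = self.coords.to_numpy()
        return np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson classical scaling, used as the deterministic MDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(lam)[None, :]


def kruskal_stress1(d_embed: np.ndarray, dissim: np.ndarray) -> float:
    """Stress-1 = sqrt(sum (d - dhat)^2 / sum d^2) with monotone disparities.

    ``dhat`` is the isotonic (monotone non-decreasing in the input
    dissimilarity order) regression of the embedded distances.
    """
    iu = np.triu_indices_from(dissim, k=1)
    d = d_embed[iu]
    delta = dissim[iu]
    dhat = IsotonicRegression(increasing=True).fit(delta, d).predict(delta)
    denom = np.sum(d**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def mds_embed(
    dissimilarity: pd.DataFrame | np.ndarray,
    dims: int = 2,
    seed: int = 0,
    max_iter: int = 3000,
) -> MdsSolution:
    """Nonmetric (Kruskal) MDS of a dissimilarity matrix.

    The SMACOF iteration is started from the classical-scaling solution,
    making the embedding deterministic for a given input and seed.  The
    reported Stress-1 is recomputed from the returned coordinates, so it
    always matches the embedding.  Coordinates are centred at the origin.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        labels = list(dissimilarity.index)
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        labels = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(d < 0):
        raise ValueError("dissimilarity must be nonnegative")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("dissimilarity must have a zero diagonal")

    init = _classical_scaling(d, dims)
    coords, _ = smacof(
        d,
        metric=False,
        n_components=dims,
        init=init,
        n_init=1,
        max_iter=max_iter,
        eps=1e-9,
        random_state=seed,
        normalized_stress=True,
    )
    coords = coords - coords.mean(axis=0, keepdims=True)
    d_embed = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    stress = kruskal_stress1(d_embed, d)
    return MdsSolution(
        coords=pd.DataFrame(
            coords, index=labels, columns=[f"dim{i + 1}" for i in range(dims)]
        ),
        stress1=stress,
    )


def suggest_clusters(solution: MdsSolution, k_range=(2, 3, 4)) -> dict:
    """Optional helper: hierarchical clustering on the embedding.

    Average-linkage clustering of the MDS coordinates; k chosen by
    silhouette score.  This is advisory only — the analysis always uses
    the configured :class:`ClusterDefinition`.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from sklearn.metrics import silhouette_score

    x = solution.coords.to_numpy()
    z = linkage(x, method="average")
    best, best_score = None, -np.inf
    for k in k_range:
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(x, labels)
        if s > best_score:
            best, best_score = labels, s
    return {
        item: int(lab) for item, lab in zip(solution.coords.index, best)
    }


# ---------------------------------------------------------------------------
# Cluster scores and stimulus selection
# ---------------------------------------------------------------------------

def cluster_scores(
    clip_item_ratings: pd.DataFrame, clusters: ClusterDefinition = DEFAULT_CLUSTERS
) -> pd.DataFrame:
    """Per-clip cluster scores: mean of the member items' ratings.

    ``clip_item_ratings`` is a clips x items table (typically the
    cross-participant mean ratings).  E.g. with playfulness =
    {amusement, interest, joy} rated (1, 2, 2), the playfulness score of
    that clip is 1.67.
    """
    out = {}
    for name in clusters.names:
        items = list(clusters.items_of(name))
        missing = [i for i in items if i not in clip_item_ratings.columns]
        if missing:
            raise KeyError(f"items missing from ratings table: {missing}")
        out[name] = clip_item_ratings[items].mean(axis=1)
    return pd.DataFrame(out)


def select_top_clips(scores: pd.Series, k: int = 6) -> list:
    """The k clips with the highest score; ties broken by ascending clip id.

    ``scores`` is indexed by clip id (restrict it to the positive clips
    before calling).  A tie at the cut-off is resolved deterministically
    toward the smaller clip id and logged.
    """
    if k > len(scores):
        raise ValueError(f"cannot select {k} clips from {len(scores)}")
    df = scores.rename("score").rename_axis("clip_id").reset_index()
    df = df.sort_values(["score", "clip_id"], ascending=[False, True], kind="mergesort")
    cutoff = df.iloc[k - 1]["score"]
    if k < len(df) and df.iloc[k]["score"] == cutoff:
        logger.info(
            "tie at rank %d (score %.4g) broken by ascending clip id", k, cutoff
        )
    return df.iloc[:k]["clip_id"].tolist()


def select_top_clips_disjoint(
    scores: pd.DataFrame, cluster_a: str, cluster_b: str, k: int = 6
) -> tuple[list, list]:
    """Disjoint top-k clip sets for a cluster-vs-cluster contrast.

    The independent top-k lists of two clusters may share clips (a clip
    can score high on both).  A contested clip is assigned to the cluster
    giving it the higher score (ties to ``cluster_a``), and the losing
    cluster refills from its next-best unassigned clips; repeated until
    the sets are disjoint.  Deterministic given the score table.
    """
    ranked = {
        name: scores[name]
        .rename("score")
        .rename_axis("clip_id")
        .reset_index()
        .sort_values(["score", "clip_id"], ascending=[False, True], kind="mergesort")[
            "clip_id"
        ]
        .tolist()
        for name in (cluster_a, cluster_b)
    }
    taken: dict = {}

    def fill(name: str, banned: set) -> list:
        out = []
        for cid in ranked[name]:
            if cid in banned:
                continue
            out.append(cid)
            if len(out) == k:
                return out
        raise ValueError(f"not enough clips to fill {k} for {name!r}")

    banned_a: set = set()
    banned_b: set = set()
    while True:
        a = fill(cluster_a, banned_a)
        b = fill(cluster_b, banned_b)
        clash = set(a) & set(b)
        if not clash:
            return a, b
        for cid in sorted(clash):
            sa, sb = scores.loc[cid, cluster_a], scores.loc[cid, cluster_b]
            if sa >= sb:
                banned_b.add(cid)
            else:
                banned_a.add(cid)
            logger.info(
                "clip %s contested between %s (%.3g) and %s (%.3g); assigned to %s",
                cid, cluster_a, sa, cluster_b, sb,
                cluster_a if sa >= sb else cluster_b,
            )
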