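"""Rating analytics: reliability, manipulation checks, FDR, MDS, cluster scores."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsemo import behavior
from nirsemo.behavior import (
    DEFAULT_CLUSTERS,
    POSITIVE_ITEMS,
    ClusterDefinition,
    RatingMatrix,
    bh_fdr,
    cluster_scores,
    icc2k,
    icc_per_item,
    manipulation_check,
    mds_embed,
    rating_correlations,
    rm_anova_1way,
    select_top_clips,
    select_top_clips_disjoint,
)
from nirsemo.synthetic import RATING_CORRELATION_TARGET


def _rating_matrix(values, n_clips=None, target="amusement"):
    values = np.asarray(values, dtype=float)
    n_clips = values.shape[1]
    clips = pd.DataFrame(
        {
            "clip_id": [f"c{i:02d}" for i in range(n_clips)],
            "condition": ["positive"] * n_clips,
            "target_emotion": [target] * n_clips,
        }
    )
    return RatingMatrix(values, [f"p{i}" for i in range(values.shape[0])], clips)


class TestIcc:
    def test_perfect_agreement_gives_one(self):
        # all raters identical, clips differ
        per_clip = np.tile(np.arange(1, 7), 2)[:10]
        x = np.tile(per_clip[:, None], (1, 5))
        assert icc2k(x) == pytest.approx(1.0)

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        x = rng.normal(4, 1, size=(20, 6))
        df = pd.DataFrame(
            [(i, j, x[i, j]) for i in range(20) for j in range(6)],
            columns=["targets", "raters", "score"],
        )
        res = pg.intraclass_corr(
            df, targets="targets", raters="raters", ratings="score"
        ).set_index("Type")
        assert icc2k(x) == pytest.approx(res.loc["ICC(A,k)", "ICC"], abs=1e-10)

    def test_pure_noise_null_distribution(self):
        """ICC of pure rater noise, 13 raters x 30 clips, 100 seeds.

        Single measures ICC(2,1): tightly near zero (within +-0.2 every
        seed, mean within +-0.05).  Average measures ICC(2,k) is roughly
        1 - 1/F with F ~ F(29, 348), so its null mean sits at
        1 - E[1/F] = 1 - 29/27 ~ -0.074 with a heavy negative tail; the
        mean is checked against that closed-form value.
        """
        v2k, v21 = [], []
        clips = pd.DataFrame(
            {
                "clip_id": [f"c{i}" for i in range(30)],
                "condition": ["positive"] * 30,
                "target_emotion": [""] * 30,
            }
        )
        for s in range(100):
            rng = np.random.default_rng(s)
            vals = rng.uniform(1, 7, size=(13, 30, 14))
            rm = RatingMatrix(vals, [f"p{i}" for i in range(13)], clips)
            v2k.append(icc_per_item(rm, "amusement"))
            v21.append(icc_per_item(rm, "amusement", variant="icc21"))
        assert np.mean(v2k) == pytest.approx(1.0 - 29.0 / 27.0, abs=0.1)
        assert np.max(np.abs(v21)) < 0.2
        assert abs(np.mean(v21)) < 0.05

    def test_variance_component_recovery(self):
        """Mixed-model simulation at n=500 recovers the closed-form ICC."""
        sc, sr, se, k = 1.0, 0.3, 0.8, 13
        rng = np.random.default_rng(7)
        x = (
            rng.normal(0, sc, (500, 1))
            + rng.normal(0, sr, (1, k))
            + rng.normal(0, se, (500, k))
        )
        expected = sc**2 / (sc**2 + (sr**2 + se**2) / k)
        assert icc2k(x) == pytest.approx(expected, abs=0.05)

    def test_degenerate_no_clip_variance_flags(self):
        x = np.ones((10, 5))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert np.isnan(icc2k(x))


class TestRmAnova:
    def test_two_conditions_equal_squared_paired_t(self):
        from scipy.stats import ttest_rel

        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 2))
        f, df1, df2, p = rm_anova_1way(x)
        t, pt = ttest_rel(x[:, 0], x[:, 1])
        assert f == pytest.approx(t**2)
        assert p == pytest.approx(pt)


class TestManipulationCheck:
    def test_strong_target_marks_all_items_lower(self):
        rng = np.random.default_rng(0)
        vals = np.clip(np.round(rng.normal(3, 0.3, size=(13, 3, 14))), 1, 7)
        ti = behavior.ALL_ITEMS.index("hope")
        vals[:, :, ti] = np.clip(vals[:, :, ti] + 3, 1, 7)
        rm = _rating_matrix(vals, target="hope")
        mc = manipulation_check(rm, "hope")
        assert (mc.posthoc["category"] == "lower").all()
        assert mc.p < 1e-6

    def test_null_keeps_false_discovery_rate(self):
        """Identically distributed items: few 'lower' labels on average."""
        clips = pd.DataFrame(
            {
                "clip_id": ["a", "b", "c"],
                "condition": ["positive"] * 3,
                "target_emotion": ["amusement"] * 3,
            }
        )
        frac = []
        for s in range(300):
            rng = np.random.default_rng(s)
            vals = np.clip(np.round(rng.normal(4, 1, size=(13, 3, 14))), 1, 7)
            rm = RatingMatrix(vals, [f"p{i}" for i in range(13)], clips)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mc = manipulation_check(rm, "amusement")
            frac.append((mc.posthoc["category"] == "lower").mean())
        assert np.mean(frac) <= 0.05


def _bh_oracle(pvals):
    """Brute-force step-up: adj_(i) = min_{j>=i} (m/j) p_(j), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = min(1.0, running)
    return adj


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_hand_computation(self):
        out = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_stay_equal_to_raw(self):
        out = bh_fdr(np.full(5, 0.2))
        assert np.allclose(out, 0.2)

    def test_matches_brute_force_on_enumerated_grid(self):
        grid = [0.001, 0.01, 0.04, 0.05, 0.2, 0.6, 1.0]
        for k in (2, 3, 4):
            for combo in itertools.product(grid, repeat=k):
                assert np.allclose(bh_fdr(np.array(combo)), _bh_oracle(combo))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=6)
    )
    def test_matches_brute_force_property(self, pvals):
        out = bh_fdr(np.array(pvals))
        assert np.allclose(out, _bh_oracle(pvals))
        assert np.all(out >= np.asarray(pvals) - 1e-12)


class TestRatingCorrelations:
    def _ratings(self, n_clips=10, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.clip(np.round(rng.uniform(1, 7, size=(5, n_clips, 14))), 1, 7)
        return _rating_matrix(vals)

    def test_symmetric_unit_diagonal(self):
        r, p, stars = rating_correlations(self._ratings())
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_duplicated_item_correlates_perfectly(self):
        rm = self._ratings()
        rm.values[:, :, rm.item_index("joy")] = rm.values[:, :, rm.item_index("amusement")]
        r, _, _ = rating_correlations(rm)
        assert r.loc["amusement", "joy"] == pytest.approx(1.0)

    def test_three_clip_hand_example_matches_product_moment(self):
        rm = self._ratings(n_clips=3)
        means = rm.clip_means("positive")
        x = means["amusement"].to_numpy()
        y = means["joy"].to_numpy()
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, _, _ = rating_correlations(rm)
        assert r.loc["amusement", "joy"] == pytest.approx(oracle)


class TestMds:
    def test_perfect_embedding_recovers_distances(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        sol = mds_embed(d, seed=1)
        assert sol.stress1 < 0.01
        got = sol.distances()
        iu = np.triu_indices(8, 1)
        assert np.corrcoef(got[iu], d[iu])[0, 1] > 0.999

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.1, 1.0, size=(4, 4))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0.0)
        s1 = mds_embed(d, seed=9)
        s2 = mds_embed(d, seed=9)
        assert np.array_equal(s1.coords.to_numpy(), s2.coords.to_numpy())
        assert s1.stress1 == s2.stress1

    def test_coordinates_centred(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        sol = mds_embed(d, seed=0)
        assert np.allclose(sol.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="symmetric"):
            mds_embed(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="nonnegative"):
            mds_embed(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError, match="zero diagonal"):
            mds_embed(np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_stress_nonincreasing_in_dimensionality(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(9, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        stresses = [mds_embed(d, dims=k, seed=0).stress1 for k in (1, 2, 3)]
        assert stresses[0] >= stresses[1] - 1e-6
        assert stresses[1] >= stresses[2] - 1e-6

    def test_published_positive_block_clusters_playfulness(self):
        """On the printed rating correlations, the playfulness trio are
        each other's nearest neighbours in the 2-D embedding."""
        pos = list(POSITIVE_ITEMS)
        d = 1.0 - RATING_CORRELATION_TARGET.loc[pos, pos]
        np.fill_diagonal(d.values, 0.0)
        sol = mds_embed(d, seed=0)
        dist = sol.distances()
        labels = list(sol.coords.index)
        trio = {"amusement", "interest", "joy"}
        for item in trio:
            i = labels.index(item)
            nearest = labels[np.argsort(dist[i])[1]]
            assert nearest in trio - {item}


class TestClusterScores:
    def _clip_table(self, **ratings):
        base = {item: 4.0 for item in POSITIVE_ITEMS}
        base.update(ratings)
        return pd.DataFrame([base], index=["clip1"])

    def test_playfulness_worked_example(self):
        table = self._clip_table(interest=1.0, joy=2.0, amusement=2.0)
        scores = cluster_scores(table)
        assert round(scores.loc["clip1", "playfulness"], 2) == 1.67

    def test_all_sevens(self):
        table = pd.DataFrame(
            [{item: 7.0 for item in POSITIVE_ITEMS}], index=["clip1"]
        )
        assert (cluster_scores(table).loc["clip1"] == 7.0).all()

    def test_harmony_mean(self):
        table = self._clip_table(love=3.0, serenity=5.0)
        assert cluster_scores(table).loc["clip1", "harmony"] == pytest.approx(4.0)

    def test_commutes_with_participant_averaging(self, small_ratings):
        per_part = [
            cluster_scores(
                pd.DataFrame(
                    small_ratings.values[p][:, : len(POSITIVE_ITEMS)],
                    index=small_ratings.clips["clip_id"],
                    columns=list(POSITIVE_ITEMS),
                )
            )
            for p in range(small_ratings.n_participants)
        ]
        mean_of_scores = sum(per_part) / len(per_part)
        score_of_means = cluster_scores(small_ratings.clip_means())
        assert np.allclose(mean_of_scores, score_of_means.loc[mean_of_scores.index])


class TestSelectTopClips:
    def test_distinct_scores_sorted(self):
        s = pd.Series([0.1, 0.9, 0.5, 0.7, 0.3, 0.8, 0.6], index=list("abcdefg"))
        assert select_top_clips(s, 3) == ["b", "f", "d"]

    def test_tie_at_cutoff_prefers_lower_clip_id(self):
        s = pd.Series([5.0, 4.0, 4.0, 3.0], index=["c4", "c2", "c1", "c3"])
        assert select_top_clips(s, 2) == ["c4", "c1"]

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError, match="cannot select"):
            select_top_clips(pd.Series([1.0], index=["a"]), 2)

    def test_disjoint_selection_never_shares_clips(self, selected_clips):
        _, scores = selected_clips
        a, b = select_top_clips_disjoint(scores, "playfulness", "harmony")
        assert len(a) == len(b) == 6
        assert not set(a) & set(b)


class TestClusterDefinition:
    def test_default_partition(self):
        assert set(DEFAULT_CLUSTERS.items_of("encouragement")) == {
            "awe", "gratitude", "hope", "inspiration", "pride",
        }
        assert DEFAULT_CLUSTERS.cluster_of("serenity") == "harmony"

    def test_incomplete_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            ClusterDefinition(mapping={"only": ("joy",)})
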