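"""Feature-table stages: filtering, aggregation, diversity, effect size,
regression, ordination."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipotaste import (
    FeatureTable,
    aggregate_to_rank,
    bray_curtis_pcoa,
    effect_size_lda,
    filter_low_count_otus,
    kw_test,
    rarefaction_curve,
    relative_abundance,
    shannon_index,
    taxa_covariate_regression,
)
from lipotaste.synthetic import generate_microbiome_counts, EffectSpec


def make_table(counts, lineages=None, features=None):
    counts = np.asarray(counts)
    features = features or [f"OTU{j}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=[f"s{i}" for i in range(counts.shape[0])],
                      columns=features)
    lin = None
    if lineages is not None:
        lin = pd.DataFrame(lineages, index=features)
    return FeatureTable(df, lin)


class TestFilter:
    def test_total_count_rule(self):
        t = make_table([[1, 2, 1], [1, 1, 0]])  # totals 2, 3, 1
        out = filter_low_count_otus(t, min_total=3)
        assert out.feature_ids == ["OTU1"]
        assert out.sample_ids == t.sample_ids

    def test_zero_threshold_is_identity(self):
        t = make_table([[1, 0], [0, 5]])
        out = filter_low_count_otus(t, 0)
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_empty_table(self):
        t = make_table(np.zeros((0, 0), dtype=int), features=[])
        assert filter_low_count_otus(t, 3).shape == (0, 0)


class TestAggregate:
    def test_counts_sum_within_rank_label(self):
        t = make_table(
            [[3, 4, 1]],
            lineages={"family": ["Bacteroidaceae", "Bacteroidaceae", "Prevotellaceae"]},
        )
        out = aggregate_to_rank(t, "family")
        assert out.counts.loc["s0", "Bacteroidaceae"] == 7
        assert out.counts.loc["s0", "Prevotellaceae"] == 1

    def test_unknown_rank_rejected(self):
        t = make_table([[1]], lineages={"family": ["X"]})
        with pytest.raises(ValueError, match="rank"):
            aggregate_to_rank(t, "genus")

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_total_counts_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(1, 6), rng.integers(1, 10)
        fams = [f"F{rng.integers(0, 4)}" for _ in range(p)]
        t = make_table(rng.integers(0, 50, size=(n, p)), lineages={"family": fams})
        out = aggregate_to_rank(t, "family")
        assert out.counts.to_numpy().sum() == t.counts.to_numpy().sum()
        np.testing.assert_array_equal(
            out.counts.sum(axis=1).to_numpy(), t.counts.sum(axis=1).to_numpy()
        )


class TestRelativeAbundance:
    def test_simple_rows(self):
        t = make_table([[1, 1, 2], [5, 0, 0]])
        ra = relative_abundance(t)
        assert list(ra.values.iloc[0]) == [0.25, 0.25, 0.5]
        assert list(ra.values.iloc[1]) == [1.0, 0.0, 0.0]

    def test_zero_rows_flagged_and_left_zero(self):
        t = make_table([[0, 0], [1, 1]])
        ra = relative_abundance(t)
        assert ra.zero_samples == ["s0"]
        assert ra.values.iloc[0].sum() == 0.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        t = make_table(rng.integers(1, 100, size=(4, 7)))
        ra = relative_abundance(t)
        np.testing.assert_allclose(ra.values.sum(axis=1), 1.0, atol=1e-9)


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert shannon_index([1, 1, 1, 1]) == pytest.approx(math.log(4), abs=1e-12)

    def test_single_taxon_is_zero(self):
        assert shannon_index([7, 0, 0]) == 0.0

    def test_direct_formula(self):
        expected = -(0.25 * math.log(0.25) * 2 + 0.5 * math.log(0.5))
        assert shannon_index([1, 1, 2]) == pytest.approx(expected, abs=1e-12)
        assert shannon_index([1, 1, 2]) == pytest.approx(1.0397, abs=1e-4)

    def test_base_option(self):
        assert shannon_index([1, 1, 1, 1], base=2) == pytest.approx(2.0)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.integers(0, 30, size=8)
            if c.sum() == 0:
                continue
            h = shannon_index(c)
            s = (c > 0).sum()
            assert 0.0 <= h <= math.log(max(s, 1)) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])


class TestRarefaction:
    def test_full_depth_sees_all_positive_features(self):
        c = [10, 0, 5, 1]
        out = rarefaction_curve(c, [16], n_reps=5, seed=0)
        assert out[0] == 3.0

    def test_depth_one_sees_one_feature(self):
        out = rarefaction_curve([4, 4], [1], n_reps=10, seed=0)
        assert out[0] == 1.0

    def test_monotone_in_depth(self):
        rng = np.random.default_rng(3)
        c = rng.integers(0, 40, size=12)
        depths = [1, 5, 20, int(c.sum())]
        out = rarefaction_curve(c, depths, n_reps=25, seed=1)
        assert all(b >= a - 1e-9 for a, b in zip(out, out[1:]))

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve([1, 1], [3], seed=0)


class TestKW:
    def test_identical_classes_null(self):
        stat, p = kw_test([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert p > 0.9

    def test_matches_mann_whitney_two_class(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        labels = np.array(["a"] * 15 + ["b"] * 15)
        h, p_kw = kw_test(x, labels)
        p_mw = stats.mannwhitneyu(
            x[:15], x[15:], alternative="two-sided", method="asymptotic",
            use_continuity=False,
        ).pvalue
        assert p_kw == pytest.approx(p_mw, rel=5e-2)

    def test_disjoint_classes_significant(self):
        vals = list(range(5)) + list(range(10, 15)) + list(range(20, 25))
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        _, p = kw_test(vals, labels)
        assert p < 0.01

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            kw_test([1, 2], ["a", "a"])


class TestEffectSizeLDA:
    def _abund(self, rng, n_per_class, planted_fc=None):
        effects = []
        if planted_fc is not None:
            effects = [EffectSpec("TM7_family_incertae_sedis", "microbiota",
                                  "up_in_taster", planted_fc)]
        from lipotaste.synthetic import (
            DEFAULT_FAMILY_PROPORTIONS,
            DEFAULT_DIRICHLET_SCALE,
        )
        fams = list(DEFAULT_FAMILY_PROPORTIONS)
        base = DEFAULT_DIRICHLET_SCALE * np.array(
            [DEFAULT_FAMILY_PROPORTIONS[f] for f in fams]
        )
        labels = ["T"] * n_per_class + ["NT"] * n_per_class
        t = generate_microbiome_counts(
            2 * n_per_class, fams, base, effects, labels, depth=5000,
            rng=rng,
        )
        return relative_abundance(t).values, labels

    def test_strong_planted_effect_scores_about_five(self):
        # class means ~1e5 vs ~1e1 per million -> log10 difference ~5
        rng = np.random.default_rng(0)
        labels = ["T"] * 30 + ["NT"] * 30
        x = np.concatenate([rng.normal(1e5, 1e4, 30), rng.normal(10, 2, 30)])
        other = 1e6 - x
        ab = pd.DataFrame({"planted": x / 1e6, "rest": other / 1e6},
                          index=[f"s{i}" for i in range(60)])
        res = effect_size_lda(ab, labels, seed=0)
        row = res.set_index("taxon").loc["planted"]
        assert row["passed"]
        assert row["lda_score_log10"] == pytest.approx(5.0, abs=0.3)
        assert row["enriched_class"] == "T"

    def test_small_mean_difference_fails_lda_cutoff(self):
        # a reliable but tiny shift: log10(50) = 1.7 < 2
        rng = np.random.default_rng(1)
        labels = ["a"] * 40 + ["b"] * 40
        x = np.concatenate([rng.normal(500, 5, 40), rng.normal(550, 5, 40)])
        ab = pd.DataFrame({"t1": x / 1e6, "t2": (1e6 - x) / 1e6},
                          index=[f"s{i}" for i in range(80)])
        res = effect_size_lda(ab, labels, seed=0).set_index("taxon")
        row = res.loc["t1"]
        assert row["kw_p"] < 0.05
        assert row["lda_score_log10"] == pytest.approx(math.log10(50), abs=0.15)
        assert not row["passed"]

    def test_null_per_taxon_pass_rate_near_alpha(self):
        # per-taxon false-pass rate stays within the binomial band around
        # the Kruskal-Wallis alpha of 0.05
        passes = total = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ab, labels = self._abund(rng, 10)
            res = effect_size_lda(ab, labels, seed=seed)
            passes += int(res["passed"].sum())
            total += len(res)
        rate = passes / total
        se = math.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3.5 * se

    def test_three_classes_rejected(self):
        ab = pd.DataFrame(np.ones((6, 2)), index=list("abcdef"))
        with pytest.raises(ValueError):
            effect_size_lda(ab, ["x", "x", "y", "y", "z", "z"])

    def test_small_class_rejected(self):
        ab = pd.DataFrame(np.ones((3, 2)), index=list("abc"))
        with pytest.raises(ValueError):
            effect_size_lda(ab, ["x", "x", "y"])


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        ab = pd.DataFrame({"t": 2 * x}, index=[f"s{i}" for i in range(10)])
        res = taxa_covariate_regression(ab, x).set_index("taxon").loc["t"]
        assert res["slope"] == pytest.approx(2.0)
        assert res["r"] == pytest.approx(1.0)
        assert res["spearman_rho"] == pytest.approx(1.0)

    def test_negative_slope_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 60)
        y = -x + rng.normal(0, 0.5, 60)
        ab = pd.DataFrame({"t": y}, index=[f"s{i}" for i in range(60)])
        res = taxa_covariate_regression(ab, x).set_index("taxon").loc["t"]
        assert res["slope"] == pytest.approx(-1.0, abs=0.1)
        assert res["p"] < 1e-6

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            ab = pd.DataFrame({"t": y}, index=[f"s{i}" for i in range(30)])
            pvals.append(
                taxa_covariate_regression(ab, x)["p"].iloc[0]
            )
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_covariate_rejected(self):
        ab = pd.DataFrame({"t": [1.0, 2.0, 3.0]}, index=list("abc"))
        with pytest.raises(ValueError):
            taxa_covariate_regression(ab, [1.0, 1.0, 1.0])


class TestOrdination:
    def test_identical_samples_zero_dissimilarity(self):
        ab = pd.DataFrame([[0.5, 0.5]] * 3, index=list("abc"))
        res = bray_curtis_pcoa(ab, n_axes=1)
        assert np.allclose(res.coordinates.to_numpy(), 0.0, atol=1e-9)

    def test_embedding_preserves_distances_when_euclidean(self):
        rng = np.random.default_rng(4)
        ab = pd.DataFrame(rng.dirichlet(np.ones(6), size=5),
                          index=[f"s{i}" for i in range(5)])
        from scipy.spatial.distance import pdist, squareform

        res = bray_curtis_pcoa(ab, n_axes=4)
        d_orig = squareform(pdist(ab.div(ab.sum(axis=1), axis=0), "braycurtis"))
        d_emb = squareform(pdist(res.coordinates.to_numpy()))
        # Bray-Curtis on 5 samples is near-Euclidean; full-rank embedding
        # reproduces pairwise dissimilarities closely
        assert np.abs(d_orig - d_emb).max() < 0.05

    def test_axes_ordered_by_explained_fraction(self, cohort):
        ab = relative_abundance(cohort.microbiome_counts).values
        res = bray_curtis_pcoa(ab, n_axes=5)
        assert all(
            b <= a + 1e-12
            for a, b in zip(res.explained_fraction, res.explained_fraction[1:])
        )
        assert res.explained_fraction.sum() <= 1.0 + 1e-9

    def test_clr_variant(self):
        rng = np.random.default_rng(5)
        ab = pd.DataFrame(rng.dirichlet(np.ones(4), size=6),
                          index=[f"s{i}" for i in range(6)])
        res = bray_curtis_pcoa(ab, n_axes=2, metric="clr")
        assert res.dissimilarity_name == "clr-euclidean"
        assert res.coordinates.shape == (6, 2)

    def test_single_sample_rejected(self):
        ab = pd.DataFrame([[1.0, 0.0]], index=["a"])
        with pytest.raises(ValueError):
            bray_curtis_pcoa(ab)
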