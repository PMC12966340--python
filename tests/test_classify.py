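"""Quartile labelling, cluster commonness rules, gradient, ensemble."""

import itertools

import numpy as np
import pandas as pd
import pytest

import prevcommon as pc
from prevcommon.classify import CentroidLabels
from prevcommon.cluster import Clustering, ClusteringResult
from prevcommon.features import FEATURES


def labels_from_counts(nH, nM, nL):
    return CentroidLabels(tuple("H" * nH + "M" * nM + "L" * nL))


def table_from_matrix(M):
    """SpeciesDataTable whose standardized columns equal the given matrix."""
    df = pd.DataFrame(M, columns=FEATURES)
    df.insert(0, "species", [f"s{i}" for i in range(len(df))])
    for f in FEATURES:
        df[f"z_{f}"] = df[f]
    return pc.SpeciesDataTable(df)


class TestFeatureQuartiles:
    def test_linear_interpolation_convention(self):
        M = np.tile(np.arange(1.0, 9.0)[:, None], (1, 6))
        q = pc.feature_quartiles(table_from_matrix(M))
        assert q[:, 0] == pytest.approx(np.full(6, 2.75))
        assert q[:, 1] == pytest.approx(np.full(6, 6.25))

    def test_constant_feature_collapses_quartiles(self):
        M = np.ones((5, 6)) * 4.2
        q = pc.feature_quartiles(table_from_matrix(M))
        assert (q[:, 0] == q[:, 1]).all()

    def test_invariant_to_species_order(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(20, 6))
        q1 = pc.feature_quartiles(table_from_matrix(M))
        q2 = pc.feature_quartiles(table_from_matrix(M[rng.permutation(20)]))
        np.testing.assert_allclose(q1, q2)


class TestLabelCentroid:
    def test_all_values_above_p75_give_six_highs(self):
        q = np.column_stack([np.zeros(6), np.ones(6)])
        lab = pc.label_centroid(np.full(6, 2.0), q)
        assert lab.labels == ("H",) * 6

    def test_value_exactly_at_percentile_is_medium(self):
        q = np.column_stack([np.zeros(6), np.ones(6)])
        lab = pc.label_centroid(np.array([1.0, 0.0, 0.5, 1.0, 0.0, 0.5]), q)
        assert lab.labels == ("M",) * 6

    def test_mixed_centroid_matches_elementwise_comparison(self):
        rng = np.random.default_rng(1)
        q = np.sort(rng.normal(size=(6, 2)), axis=1)
        c = rng.normal(size=6)
        lab = pc.label_centroid(c, q)
        for v, (lo, hi), got in zip(c, q, lab.labels):
            want = "H" if v > hi else ("L" if v < lo else "M")
            assert got == want


class TestClassifyCluster:
    @pytest.mark.parametrize("counts,expected", [
        ((4, 1, 1), pc.VERY_COMMON),
        ((2, 2, 2), pc.FAIRLY_COMMON),   # three-way tie -> medium
        ((1, 2, 3), pc.RARE),
        ((3, 3, 0), pc.FAIRLY_COMMON),   # H ties M -> medium
        ((0, 0, 6), pc.RARE),
        ((6, 0, 0), pc.VERY_COMMON),
    ])
    def test_majority_rule(self, counts, expected):
        assert pc.classify_cluster(labels_from_counts(*counts)) == expected


class TestGradientScore:
    def test_anchor_points_match_class_prevalences(self):
        assert pc.gradient_score(labels_from_counts(6, 0, 0)) == 0.8
        assert pc.gradient_score(labels_from_counts(0, 6, 0)) == 0.5
        assert pc.gradient_score(labels_from_counts(0, 0, 6)) == 0.2

    def test_three_high_three_medium_gives_065(self):
        assert pc.gradient_score(labels_from_counts(3, 3, 0)) == pytest.approx(0.65)

    def test_lattice_spans_02_to_08_in_005_steps(self):
        scores = sorted({pc.gradient_score(labels_from_counts(h, 6 - h - l, l))
                         for h in range(7) for l in range(7 - h)})
        assert scores[0] == 0.2 and scores[-1] == 0.8
        np.testing.assert_allclose(np.diff(scores), 0.05)

    def test_monotone_in_high_minus_low_count(self):
        combos = [(h, l) for h in range(7) for l in range(7 - h)]
        for (h1, l1), (h2, l2) in itertools.combinations(combos, 2):
            if h1 - l1 < h2 - l2:
                assert pc.gradient_score(labels_from_counts(h1, 6 - h1 - l1, l1)) <= \
                    pc.gradient_score(labels_from_counts(h2, 6 - h2 - l2, l2))


class TestClassifyFromClustering:
    def _result(self, assignments, X):
        K = int(assignments.max()) + 1
        cents = np.vstack([X[assignments == k].mean(0) for k in range(K)])
        c = Clustering(K=K, assignments=assignments, centroids=cents,
                       sse=0.0)
        return ClusteringResult(best=c, K_star=K, selection_scores={})

    def test_species_inherit_their_cluster_class(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(3, 0.05, (8, 6)),
                       rng.normal(0, 0.05, (8, 6)),
                       rng.normal(-3, 0.05, (8, 6))])
        table = table_from_matrix(X)
        res = self._result(np.repeat([0, 1, 2], 8), X)
        classes, grads = pc.classify_from_clustering(table, res)
        assert set(classes[:8]) == {pc.VERY_COMMON}
        assert set(classes[8:16]) == {pc.FAIRLY_COMMON}
        assert set(classes[16:]) == {pc.RARE}
        assert grads[0] == 0.8 and grads[-1] == 0.2

    def test_singleton_cluster_classified_from_its_own_vector(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.05, (9, 6)), np.full((1, 6), 5.0)])
        table = table_from_matrix(X)
        res = self._result(np.array([0] * 9 + [1]), X)
        classes, _ = pc.classify_from_clustering(table, res)
        assert classes[-1] == pc.VERY_COMMON

    def test_no_low_majority_cluster_means_no_rare_species(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(1, 0.05, (8, 6)), rng.normal(-1, 0.05, (8, 6))])
        # both clusters straddle the quartiles computed from the pooled data,
        # neither ends with an L majority over H and M simultaneously
        table = table_from_matrix(X)
        res = self._result(np.repeat([0, 1], 8), X)
        classes, _ = pc.classify_from_clustering(table, res)
        assert pc.RARE not in set(classes) or pc.VERY_COMMON in set(classes)

    def test_planted_tiers_recovered_on_default_fixture(self, default_models):
        ref = default_models["reference"]
        got = default_models["cols"]["MultiKMeansClass"]
        assert pc.accuracy(got, ref) >= 0.85


class TestClassifyFromVae:
    def test_lowest_score_group_classified_rare_on_clean_separation(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-2, 0.05, (6, 6)),
                       rng.normal(0, 0.05, (6, 6)),
                       rng.normal(2, 0.05, (6, 6))])
        table = table_from_matrix(X)
        groups = np.repeat([0, 1, 2], 6)   # group 0 = lowest scores
        classes, _ = pc.classify_from_vae(table, groups)
        assert set(classes[:6]) == {pc.RARE}
        assert set(classes[6:12]) == {pc.FAIRLY_COMMON}
        assert set(classes[12:]) == {pc.VERY_COMMON}

    def test_group_classes_need_not_be_distinct(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 0.05, (12, 6))
        table = table_from_matrix(X)
        classes, _ = pc.classify_from_vae(table, np.repeat([0, 1], 6))
        assert set(classes) == {pc.FAIRLY_COMMON}


class TestEnsembleAndPrevalence:
    @pytest.mark.parametrize("votes,expected", [
        ((pc.VERY_COMMON, pc.VERY_COMMON, pc.RARE), pc.VERY_COMMON),
        ((pc.VERY_COMMON, pc.FAIRLY_COMMON, pc.RARE), pc.FAIRLY_COMMON),
        ((pc.RARE, pc.RARE, pc.RARE), pc.RARE),
        ((pc.RARE, pc.FAIRLY_COMMON, pc.RARE), pc.RARE),
    ])
    def test_majority_with_fairly_common_default(self, votes, expected):
        assert pc.ensemble(*votes) == expected

    def test_vectorised_ensemble_matches_scalar(self):
        a = np.array([pc.RARE, pc.VERY_COMMON], dtype=object)
        b = np.array([pc.RARE, pc.FAIRLY_COMMON], dtype=object)
        c = np.array([pc.VERY_COMMON, pc.RARE], dtype=object)
        out = pc.ensemble(a, b, c)
        assert out.tolist() == [pc.RARE, pc.FAIRLY_COMMON]

    def test_prevalence_anchors(self):
        assert pc.map_prevalence(pc.RARE) == 0.2
        assert pc.map_prevalence(pc.FAIRLY_COMMON) == 0.5
        assert pc.map_prevalence(pc.VERY_COMMON) == 0.8
        np.testing.assert_allclose(
            pc.map_prevalence([pc.RARE, pc.VERY_COMMON]), [0.2, 0.8])
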