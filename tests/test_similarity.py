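"""Fit-vector scoring, integral dissimilarity, clustering, heatmap."""

import math

import numpy as np
import pytest

from dielflux.curves import ensemble_from_params, fit_transcriptome, FAMILIES
from dielflux.errors import ValidationError
from dielflux.expression import ExpressionSeries
from dielflux.similarity import (FitVector, VECTOR_LENGTH, assemble_heatmap,
                                 cluster, distance_value,
                                 integral_dissimilarity, pairwise_matrix,
                                 score_pair, vectorize)


def vec(*values):
    v = np.zeros(VECTOR_LENGTH)
    v[:len(values)] = values
    return FitVector("v", v)


class TestVectorize:
    def test_constant_only_ensemble_layout(self):
        e = ensemble_from_params("g", "constant", (5.0,))
        fv = vectorize(e)
        assert fv.vector[0] == pytest.approx(5.0)  # constant slot is first
        assert np.count_nonzero(fv.vector) == 1
        assert len(fv.vector) == VECTOR_LENGTH

    def test_identical_ensembles_identical_vectors(self, small_fitted_transcriptome):
        _, _, ensembles = small_fitted_transcriptome
        v1, v2 = vectorize(ensembles[0]), vectorize(ensembles[0])
        np.testing.assert_array_equal(v1.vector, v2.vector)


class TestScorePair:
    def test_self_score_is_one(self):
        u = vec(3.0, 4.0)
        s = score_pair(u, u, dm=50.0)
        assert s.d == 0.0
        assert s.distance_value == 1.0
        assert s.cos_theta == 1.0
        assert s.score == 1.0

    def test_distance_equal_dm_scores_zero(self):
        u, v = vec(10.0), vec(0.0, 10.0)  # orthogonal, d = sqrt(200)
        d = math.sqrt(200.0)
        s = score_pair(u, v, dm=d)
        assert s.distance_value == pytest.approx(0.0, abs=1e-12)
        assert s.score == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_at_unit_distance(self):
        a = vec(1 / math.sqrt(2))
        b = FitVector("b", np.zeros(VECTOR_LENGTH))
        b.vector[1] = 1 / math.sqrt(2)
        s = score_pair(a, b, dm=10.0)  # d = 1 exactly
        assert s.d == pytest.approx(1.0)
        assert s.cos_theta == pytest.approx(0.0, abs=1e-12)
        assert s.distance_value == pytest.approx(1.0)
        assert s.score == pytest.approx(0.0, abs=1e-12)

    def test_half_log_distance_scores_half(self):
        # aligned vectors at d = sqrt(dm): distance_value = 1/2
        dm = 100.0
        u, v = vec(5.0), vec(5.0 + math.sqrt(dm))
        s = score_pair(u, v, dm=dm)
        assert s.cos_theta == pytest.approx(1.0)
        assert s.distance_value == pytest.approx(0.5)
        assert s.score == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError, match="v"):
            score_pair(vec(1.0), FitVector("v", np.zeros(VECTOR_LENGTH)), 10.0)

    def test_distance_value_monotone_on_log_range(self):
        dvs = [distance_value(d, 100.0) for d in np.linspace(1, 100, 25)]
        assert all(a >= b - 1e-12 for a, b in zip(dvs, dvs[1:]))

    def test_score_bounded_for_random_pairs(self):
        rng = np.random.default_rng(4)
        vs = [FitVector(str(i), rng.normal(size=VECTOR_LENGTH))
              for i in range(12)]
        ds = [np.linalg.norm(a.vector - b.vector)
              for i, a in enumerate(vs) for b in vs[i + 1:]]
        dm = max(ds)
        for i, a in enumerate(vs):
            for b in vs[i + 1:]:
                s = score_pair(a, b, dm)
                assert -1.0 - 1e-12 <= s.score <= 1.0 + 1e-12


class TestIntegralDissimilarity:
    def test_identical_curves_zero(self):
        e = ensemble_from_params("a", "one_term_cosine", (50.0, 20.0, 6.0))
        assert integral_dissimilarity(e, e) == pytest.approx(0.0)

    def test_affine_rescaling_invariance(self):
        e1 = ensemble_from_params("a", "one_term_cosine", (50.0, 20.0, 6.0))
        # 2x + 7: mesor 107, amplitude 40, same phase
        e2 = ensemble_from_params("b", "one_term_cosine", (107.0, 40.0, 6.0))
        assert integral_dissimilarity(e1, e2) == pytest.approx(0.0, abs=1e-12)

    def test_square_wave_vs_complement_is_one(self):
        # hat plateaus on complementary halves of the day
        e1 = ensemble_from_params("a", "hat", (10.0, 100.0, 0.0, 12.0))
        e2 = ensemble_from_params("b", "hat", (10.0, 100.0, 12.0, 24.0))
        assert integral_dissimilarity(e1, e2) == pytest.approx(1.0)

    def test_symmetric(self):
        e1 = ensemble_from_params("a", "fixed_decay", (10.0, 90.0))
        e2 = ensemble_from_params("b", "one_term_cosine", (50.0, 30.0, 3.0))
        assert integral_dissimilarity(e1, e2) == pytest.approx(
            integral_dissimilarity(e2, e1))

    def test_dt_must_divide_period(self):
        e = ensemble_from_params("a", "constant", (5.0,))
        with pytest.raises(ValidationError):
            integral_dissimilarity(e, e, dt=0.7)


class TestPairwiseMatrix:
    def test_identical_genes_extreme_values(self):
        e1 = ensemble_from_params("a", "one_term_cosine", (50.0, 20.0, 6.0))
        e2 = ensemble_from_params("b", "one_term_cosine", (50.0, 20.0, 6.0))
        e3 = ensemble_from_params("c", "fixed_decay", (10.0, 200.0))
        mi = pairwise_matrix([e1, e2, e3], method="integral")
        assert mi.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert mi.values[0, 2] > 0.1

    def test_symmetry_and_diagonal(self, small_fitted_transcriptome):
        _, _, ensembles = small_fitted_transcriptome
        for method in ("score", "integral"):
            m = pairwise_matrix(ensembles, method=method)
            np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)
            if method == "score":
                np.testing.assert_allclose(np.diag(m.values), 1.0)
            else:
                np.testing.assert_allclose(np.diag(m.values), 0.0)


def planted_cluster_ensembles(n_per=20, noise_cv=0.01, seed=5):
    """Three expression archetypes (shared phase within a group) with
    mild parameter jitter, fitted against all families."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 25.0, 2.0)
    series, labels = [], []
    sigma = math.sqrt(math.log(1 + noise_cv ** 2))
    archetypes = [
        ("one_term_cosine", lambda: (rng.uniform(80, 120),
                                     rng.uniform(40, 60),
                                     6.0 + rng.uniform(-0.5, 0.5))),
        ("variable_decay", lambda: (rng.uniform(20, 40),
                                    rng.uniform(120, 200),
                                    rng.uniform(1.5, 2.5))),
        ("constant", lambda: (rng.uniform(50, 150),)),
    ]
    for label, (family, draw) in enumerate(archetypes):
        for i in range(n_per):
            params = draw()
            y = np.maximum(FAMILIES[family].evaluate(params, t), 0.0)
            # a flat profile has no shape: min-max normalization amplifies
            # any noise into an arbitrary curve, so "low noise" for the
            # constant archetype means exactly zero
            if family != "constant":
                y = y * np.exp(rng.normal(0, sigma, size=len(t)))
            series.append(ExpressionSeries(f"g{label}_{i}", t, y))
            labels.append(label)
    ensembles = fit_transcriptome(series, n_restarts=8, seed=0)
    return ensembles, np.array(labels)


class TestClustering:
    def test_identical_pair_merges_first(self):
        e1 = ensemble_from_params("a", "one_term_cosine", (50.0, 20.0, 6.0))
        e2 = ensemble_from_params("b", "one_term_cosine", (50.0, 20.0, 6.0))
        e3 = ensemble_from_params("c", "hat", (5.0, 100.0, 2.0, 10.0))
        m = pairwise_matrix([e1, e2, e3], method="integral")
        result = cluster(m, n_leaves=2)
        assert result.leaf_labels[0] == result.leaf_labels[1]
        assert result.leaf_labels[2] != result.leaf_labels[0]
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_n_leaves_equals_n_genes(self, small_fitted_transcriptome):
        _, _, ensembles = small_fitted_transcriptome
        m = pairwise_matrix(ensembles[:6], method="integral")
        result = cluster(m, n_leaves=6)
        assert len(set(result.leaf_labels)) == 6

    def test_n_leaves_exceeding_genes_rejected(self, small_fitted_transcriptome):
        _, _, ensembles = small_fitted_transcriptome
        m = pairwise_matrix(ensembles[:4], method="integral")
        with pytest.raises(ValidationError):
            cluster(m, n_leaves=5)

    def test_planted_clusters_recovered(self):
        ensembles, labels = planted_cluster_ensembles()
        m = pairwise_matrix(ensembles, method="integral")
        result = cluster(m, n_leaves=3)
        purity = 0
        for leaf in np.unique(result.leaf_labels):
            members = labels[result.leaf_labels == leaf]
            purity += np.bincount(members).max()
        assert purity / len(labels) >= 0.95


class TestHeatmap:
    def test_smoke_and_symmetry(self, tmp_path, small_fitted_transcriptome):
        _, _, ensembles = small_fitted_transcriptome
        m = pairwise_matrix(ensembles, method="integral")
        result = cluster(m, n_leaves=4)
        weights = {e.gene_id: e.weights for e in ensembles}
        out = tmp_path / "map.png"
        img = assemble_heatmap(m, result, weights, out)
        assert out.exists()
        n = len(m.genes)
        np.testing.assert_allclose(img[:n, :n], np.swapaxes(img[:n, :n], 0, 1),
                                   atol=1e-12)

    def test_dominant_family_dominates_sidebar(self, tmp_path):
        genes = [ensemble_from_params("spike", "kronecker_delta",
                                      (10.0, 200.0, 8.0)),
                 ensemble_from_params("flatA", "constant", (50.0,)),
                 ensemble_from_params("cosA", "one_term_cosine",
                                      (60.0, 30.0, 6.0))]
        m = pairwise_matrix(genes, method="integral")
        result = cluster(m, n_leaves=2)
        weights = {e.gene_id: e.weights for e in genes}
        sidebar_px = 6
        img = assemble_heatmap(m, result, weights, tmp_path / "m.png",
                               sidebar_px=sidebar_px)
        n = len(genes)
        row = list(result.leaf_order).index(m.genes.index("spike"))
        sidebar = img[row, n:, :3]
        from matplotlib import colormaps
        from dielflux.curves import FAMILY_ORDER
        kron_color = np.array(colormaps["tab10"](
            FAMILY_ORDER.index("kronecker_delta") % 10)[:3])
        matches = np.isclose(sidebar, kron_color, atol=1e-6).all(axis=1)
        assert matches.mean() > 0.5
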