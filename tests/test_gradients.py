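"""Gradient decomposition, alignment, and condition differencing."""

import numpy as np
import pytest
from scipy import stats

from gradflex import (
    align_gradients,
    cosine_affinity,
    decompose_gradients,
    gradient_difference,
    gradients_from_connectivity,
    map_correlation,
    sparsify_rows,
)


class TestSparsifyRows:
    def test_full_density_only_zeroes_diagonal(self, rng):
        m = rng.uniform(size=(5, 5))
        out = sparsify_rows(m, 1.0)
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_array_equal(out[off], m[off])
        assert np.all(out.diagonal() == 0)

    def test_half_density_keeps_two_largest(self):
        m = np.zeros((4, 4))
        m[0] = [0.0, 0.9, 0.5, 0.1]    # diagonal excluded from ranking
        out = sparsify_rows(m, 0.5)
        np.testing.assert_array_equal(out[0], [0.0, 0.9, 0.5, 0.0])

    def test_nonzero_count_per_row(self, rng):
        P = 11
        m = rng.normal(size=(P, P))     # continuous, no ties
        for density in (0.1, 0.3, 0.5):
            out = sparsify_rows(m, density)
            expect = min(int(np.ceil(density * P)), P - 1)
            counts = (out != 0).sum(axis=1)
            assert np.all(counts == expect)

    def test_nonpositive_density_errors(self):
        with pytest.raises(ValueError):
            sparsify_rows(np.eye(3), 0.0)


class TestCosineAffinity:
    def test_identical_rows(self):
        m = np.vstack([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.0, 1.0, 0.0]])
        aff = cosine_affinity(m)
        assert aff[0, 1] == pytest.approx(1.0)

    def test_disjoint_support_rows(self):
        m = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert cosine_affinity(m)[0, 1] == pytest.approx(0.0)

    def test_closed_form_value(self):
        m = np.array([[1.0, 0.0], [1.0, 1.0]])
        assert cosine_affinity(m)[0, 1] == pytest.approx(1 / np.sqrt(2))

    def test_zero_row_names_parcel(self):
        m = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="1"):
            cosine_affinity(m)


class TestDecomposeGradients:
    def test_rank_one_centred_structure(self):
        v = np.linspace(-1, 1, 8)
        aff = np.outer(v, v) + 1.0       # rank-1 after centring
        g = decompose_gradients(aff, 3)
        assert g.variance_ratio[0] > 0.999

    def test_recovers_planted_axis_from_decaying_connectivity(self):
        g_true = np.linspace(-1, 1, 60)
        conn = np.exp(-1.5 * np.abs(g_true[:, None] - g_true[None, :]))
        gs = gradients_from_connectivity(conn, 5)
        rho = stats.spearmanr(gs.principal(), g_true).statistic
        assert abs(rho) >= 0.9

    def test_full_parcellation_scale_shapes_and_ordering(self, rng):
        m = rng.normal(size=(400, 400))
        m = (m + m.T) / 2
        gs = decompose_gradients(m, 10)
        assert gs.scores.shape == (400, 10)
        assert np.all(np.diff(gs.variance_ratio) <= 1e-12)
        assert gs.variance_ratio.sum() <= 1 + 1e-9

    def test_asymmetric_input_rejected(self, rng):
        m = rng.normal(size=(5, 5))
        with pytest.raises(ValueError, match="symmetric"):
            decompose_gradients(m, 2)

    def test_deterministic_repeats(self, rng):
        m = rng.normal(size=(30, 30))
        m = (m + m.T) / 2
        g1 = decompose_gradients(m, 4)
        g2 = decompose_gradients(m, 4)
        np.testing.assert_array_equal(g1.scores, g2.scores)

    def test_scores_invariant_to_parcel_relabelling(self, rng):
        g_true = np.linspace(-1, 1, 40)
        conn = np.exp(-np.abs(g_true[:, None] - g_true[None, :]))
        conn += 0.01 * np.diag(rng.uniform(size=40))
        conn = (conn + conn.T) / 2
        perm = rng.permutation(40)
        g1 = gradients_from_connectivity(conn, 2)
        g2 = gradients_from_connectivity(conn[np.ix_(perm, perm)], 2)
        # same scores up to the permutation and a possible global sign
        s1 = g1.principal()[perm]
        s2 = g2.principal()
        agree = min(np.max(np.abs(s1 - s2)), np.max(np.abs(s1 + s2)))
        assert agree < 1e-8


class TestAlignGradients:
    def _grad(self, scores):
        from gradflex.gradients import GradientSet

        k = scores.shape[1]
        return GradientSet(
            scores=scores, eigenvalues=np.ones(k),
            variance_ratio=np.full(k, 1 / k),
        )

    def test_template_identity(self, rng):
        scores = rng.normal(size=(10, 3))
        g = self._grad(scores)
        out = align_gradients(g, self._grad(scores.copy()))
        np.testing.assert_allclose(out.scores, scores)

    def test_sign_flip_restored(self, rng):
        scores = rng.normal(size=(10, 3))
        out = align_gradients(self._grad(-scores), self._grad(scores))
        for k in range(3):
            r = np.corrcoef(out.scores[:, k], scores[:, k])[0, 1]
            assert r == pytest.approx(1.0)

    def test_procrustes_recovers_random_rotation(self, rng):
        scores = rng.normal(size=(20, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        rotated = scores @ q
        out = align_gradients(self._grad(rotated), self._grad(scores), "procrustes")
        for k in range(4):
            r = abs(np.corrcoef(out.scores[:, k], scores[:, k])[0, 1])
            assert r >= 0.99

    def test_parcel_count_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            align_gradients(
                self._grad(rng.normal(size=(5, 2))),
                self._grad(rng.normal(size=(6, 2))),
            )


class TestGradientDifference:
    def _aligned(self, scores, template_id="t"):
        from gradflex.gradients import GradientSet

        g = GradientSet(
            scores=scores, eigenvalues=np.ones(scores.shape[1]),
            variance_ratio=np.ones(scores.shape[1]) / scores.shape[1],
            alignment="sign-matched", template_id=template_id,
        )
        return g

    def test_identical_gradients_zero_map(self, rng):
        s = rng.normal(size=(8, 2))
        d = gradient_difference(self._aligned(s), self._aligned(s.copy()))
        np.testing.assert_allclose(d, 0.0, atol=1e-15)

    def test_unaligned_inputs_refused(self, rng):
        from gradflex.gradients import GradientSet

        s = rng.normal(size=(8, 2))
        raw = GradientSet(scores=s, eigenvalues=np.ones(2),
                          variance_ratio=np.array([0.6, 0.4]))
        with pytest.raises(ValueError, match="align"):
            gradient_difference(raw, self._aligned(s))


class TestMapCorrelation:
    def test_self_correlation_is_one(self, rng):
        m = rng.normal(size=10)
        assert map_correlation(m, m).r == pytest.approx(1.0)

    def test_negation_is_minus_one(self, rng):
        m = rng.normal(size=10)
        assert map_correlation(m, -m).r == pytest.approx(-1.0)

    def test_matches_scipy_pearson_and_spearman(self):
        a = np.array([0.2, -1.0, 0.5, 2.0, 0.9])
        b = np.array([1.0, 0.3, -0.2, 1.5, 0.8])
        assert map_correlation(a, b).r == pytest.approx(
            stats.pearsonr(a, b).statistic
        )
        assert map_correlation(a, b, "spearman").r == pytest.approx(
            stats.spearmanr(a, b).statistic
        )

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            map_correlation(np.ones(5), np.arange(5.0))
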