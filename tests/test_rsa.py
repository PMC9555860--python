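"""Second-order RSA: semantic and brain participant-similarity models."""

import numpy as np
import pytest
from scipy import stats

from gradflex import (
    alignment_significance,
    brain_model,
    second_order_alignment,
    semantic_model,
    trial_similarity,
)
from gradflex.connectivity import TrialSimilarity


def _sim_from_vec(values, runs, pid=0):
    n = len(runs)
    m = np.eye(n)
    iu = np.triu_indices(n, 1)
    m[iu] = values
    m = m + m.T - np.eye(n)
    return TrialSimilarity(pid, m, runs[:, None] != runs[None, :])


class TestSemanticModel:
    def test_identical_raters_correlate_one(self):
        ratings = np.vstack([[1, 2, 3, 4], [1, 2, 3, 4], [4, 2, 1, 3]])
        m = semantic_model(ratings)
        assert m.matrix[0, 1] == pytest.approx(1.0)

    def test_shape_symmetry_unit_diagonal(self, rng):
        ratings = rng.integers(0, 5, size=(6, 20)).astype(float)
        m = semantic_model(ratings)
        assert m.matrix.shape == (6, 6)
        np.testing.assert_allclose(m.matrix, m.matrix.T)
        np.testing.assert_allclose(np.diag(m.matrix), 1.0)

    def test_hand_computed_three_raters(self):
        ratings = np.array([[0.0, 1, 2, 4], [1, 1, 3, 3], [4, 3, 2, 0]])
        m = semantic_model(ratings)
        for i in range(3):
            for j in range(3):
                expect = stats.pearsonr(ratings[i], ratings[j]).statistic
                assert m.matrix[i, j] == pytest.approx(expect, abs=1e-12)

    def test_constant_rater_rejected(self):
        ratings = np.vstack([[2, 2, 2, 2], [1, 2, 3, 4], [0, 2, 0, 2]])
        with pytest.raises(ValueError):
            semantic_model(ratings)


class TestBrainModel:
    def test_shared_structure_gives_all_ones(self, rng):
        runs = np.repeat(np.arange(3), 2)
        vals = rng.uniform(-0.5, 0.5, 15)
        sims = [_sim_from_vec(vals, runs, p) for p in range(4)]
        bm = brain_model(sims)
        np.testing.assert_allclose(bm.matrix, 1.0, atol=1e-12)

    def test_permuted_structure_decorrelates(self, rng):
        # permuting one participant's pair values makes the expected
        # cross-participant correlation zero
        runs = np.repeat(np.arange(3), 8)
        rs = []
        for _ in range(200):
            vals = rng.uniform(-0.8, 0.8, 24 * 23 // 2)
            sims = [_sim_from_vec(vals, runs, 0),
                    _sim_from_vec(rng.permutation(vals), runs, 1)]
            rs.append(brain_model(sims).matrix[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_matches_double_loop_oracle(self, rng):
        runs = np.array([0, 0, 1, 1])
        sims = [_sim_from_vec(rng.uniform(-0.9, 0.9, 6), runs, p) for p in range(3)]
        bm = brain_model(sims)
        for i in range(3):
            for j in range(3):
                vi, vj = sims[i].valid_values(), sims[j].valid_values()
                expect = 1.0 if i == j else stats.pearsonr(vi, vj).statistic
                assert bm.matrix[i, j] == pytest.approx(expect, abs=1e-12)


class TestSecondOrderAlignment:
    def _random_models(self, rng, n_sub, n_loc):
        sem = semantic_model(rng.normal(size=(n_sub, 30)))
        brains = []
        runs = np.repeat(np.arange(3), 4)
        for loc in range(n_loc):
            sims = [_sim_from_vec(rng.uniform(-0.8, 0.8, 66), runs, p)
                    for p in range(n_sub)]
            brains.append(brain_model(sims, location=loc))
        return sem, brains

    def test_identical_models_hit_the_clip_ceiling(self, rng):
        sem = semantic_model(rng.normal(size=(5, 30)))
        from gradflex.rsa import ParticipantSimilarityModel

        bm = ParticipantSimilarityModel(sem.matrix.copy(), "brain", 0)
        out = second_order_alignment(sem, [bm])
        assert out.values[0] == pytest.approx(np.arctanh(1 - 1e-6))

    def test_permuted_model_aligns_near_zero(self, rng):
        vals = []
        for _ in range(100):
            sem = semantic_model(rng.normal(size=(8, 25)))
            perm = rng.permutation(8)
            from gradflex.rsa import ParticipantSimilarityModel

            bm = ParticipantSimilarityModel(
                sem.matrix[np.ix_(perm, perm)], "brain", 0
            )
            vals.append(second_order_alignment(sem, [bm]).values[0])
        assert abs(np.mean(vals)) < 0.05

    def test_alignment_increases_with_planted_coupling(self):
        # mean alignment in coupled parcels grows with coupling strength
        from gradflex import SyntheticSpec, simulate_dataset

        means = []
        for beta in (0.0, 3.0):
            spec = SyntheticSpec(
                n_participants=10, n_trials=36, n_parcels=12,
                voxels_per_parcel=27, coupling_strength=beta,
                n_coupling_parcels=4, seed=3,
            )
            ds = simulate_dataset(spec)
            sem = semantic_model(
                ds.behavior.ratings[ds.behavior.trial_ids].to_numpy(float)
            )
            brains = []
            for pid in (1, 2, 3, 4):
                sims = [
                    trial_similarity(
                        ps.patterns[:, ps.voxel_to_parcel == pid],
                        ps.run_labels, parcel_id=pid,
                    )
                    for ps in ds.semantic
                ]
                brains.append(brain_model(sims, location=pid))
            means.append(second_order_alignment(sem, brains).values.mean())
        assert means[1] > means[0] + 0.1

    def test_invariant_to_common_participant_relabelling(self, rng):
        sem, brains = self._random_models(rng, 6, 3)
        out1 = second_order_alignment(sem, brains)
        perm = rng.permutation(6)
        from gradflex.rsa import ParticipantSimilarityModel

        sem_p = ParticipantSimilarityModel(sem.matrix[np.ix_(perm, perm)], "semantic")
        brains_p = [
            ParticipantSimilarityModel(b.matrix[np.ix_(perm, perm)], "brain",
                                       b.location)
            for b in brains
        ]
        out2 = second_order_alignment(sem_p, brains_p)
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-10)


class TestAlignmentSignificance:
    def test_maximum_statistic_with_99_permutations(self, rng):
        # observed z larger than every permuted z -> p = 1/100
        sem, brains = self._models(rng)
        out = second_order_alignment(sem, brains)
        out.values[0] = 10.0             # force the observed max
        sig = alignment_significance(out, sem, brains, n_perm=99, seed=0)
        assert sig.p_values[0] == pytest.approx(0.01)

    def _models(self, rng):
        sem = semantic_model(rng.normal(size=(6, 30)))
        runs = np.repeat(np.arange(3), 4)
        brains = [
            brain_model(
                [_sim_from_vec(rng.uniform(-0.8, 0.8, 66), runs, p)
                 for p in range(6)],
                location=loc,
            )
            for loc in range(3)
        ]
        return sem, brains

    def test_planted_coupling_detected_null_parcels_clean(self, small_dataset):
        ds = small_dataset
        sem = semantic_model(
            ds.behavior.ratings[ds.behavior.trial_ids].to_numpy(float)
        )
        brains = []
        for pid in ds.atlas.parcel_ids:
            sims = [
                trial_similarity(ps.patterns[:, ps.voxel_to_parcel == pid],
                                 ps.run_labels, parcel_id=int(pid))
                for ps in ds.semantic
            ]
            brains.append(brain_model(sims, location=int(pid)))
        out = second_order_alignment(sem, brains)
        sig = alignment_significance(out, sem, brains, n_perm=499, seed=1)
        planted = ds.truth.coupling_indicator.astype(bool)
        assert sig.fdr_mask[planted].mean() >= 0.9
        assert sig.fdr_mask[~planted].mean() <= 0.2
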