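"""MCR-ALS tests: initialization, factorization fixed points, regularization
limits, ground-truth recovery and component matching."""

import itertools

import numpy as np
import pytest

from ramanod import MCRALS, initialize_components, match_components, mcr_als, svd_denoise
from ramanod.datatypes import ComponentSet
from ramanod.mcr import cosine_similarity_matrix


def gaussian_templates(n, n_bins=80, width=0.04):
    x = np.linspace(0, 1, n_bins)
    centers = np.linspace(0.15, 0.85, n)
    return np.vstack([np.exp(-0.5 * ((x - c) / width) ** 2) for c in centers])


class TestInitialize:
    def test_user_spectra_pass_through_row_normalized(self, rng):
        W0 = rng.uniform(0, 2, (3, 40))
        W = initialize_components(rng.uniform(0, 1, (10, 40)), 3, method="user", W0=W0)
        np.testing.assert_allclose(
            W, W0 / np.linalg.norm(W0, axis=1, keepdims=True), rtol=1e-12
        )

    def test_purest_rows_recover_distinct_templates(self):
        x = np.linspace(0, 1, 80)
        templates = np.vstack(
            [np.exp(-0.5 * ((x - c) / 0.05) ** 2) + 0.1 * i for i, c in enumerate([0.2, 0.5, 0.8])]
        )
        A = templates[np.array([0, 1, 2, 0, 1, 2, 1, 0, 2, 2])]
        W = initialize_components(A, 3, method="purest_variable")
        sim = cosine_similarity_matrix(W, templates)
        # every template matched by a distinct initial spectrum
        best = np.argmax(sim, axis=0)
        assert len(set(best.tolist())) == 3
        assert np.all(sim[best, np.arange(3)] >= 0.99)

    def test_random_init_seed_deterministic(self, rng):
        A = rng.uniform(0, 1, (8, 30))
        W1 = initialize_components(A, 3, method="random", seed=5)
        W2 = initialize_components(A, 3, method="random", seed=5)
        np.testing.assert_array_equal(W1, W2)

    def test_too_many_components_raises(self, rng):
        with pytest.raises(ValueError, match="rank bound"):
            initialize_components(rng.uniform(0, 1, (4, 30)), 5)

    def test_unknown_method_raises(self, rng):
        with pytest.raises(ValueError, match="init method"):
            initialize_components(rng.uniform(0, 1, (4, 30)), 2, method="magic")


class TestALS:
    def test_exact_factorization_is_fixed_point(self, rng):
        W0 = gaussian_templates(3)
        W0 /= np.linalg.norm(W0, axis=1, keepdims=True)
        H0 = rng.uniform(0.1, 1.0, (20, 3))
        A = H0 @ W0
        result = mcr_als(A, n_components=3, alpha_l1_h=0.0, init="user", W0=W0)
        assert result.residual_norm < 1e-8
        sim = cosine_similarity_matrix(result.W, W0)
        from scipy.optimize import linear_sum_assignment

        r, c = linear_sum_assignment(-sim)
        assert np.all(sim[r, c] >= 0.999)

    def test_huge_penalty_zeroes_profiles(self, rng):
        A = rng.uniform(0, 1, (10, 25))
        baseline = mcr_als(A, n_components=2, alpha_l1_h=0.0, init="random", seed=0)
        crushed = mcr_als(A, n_components=2, alpha_l1_h=1e6, init="random", seed=0)
        assert np.abs(crushed.H).sum() < 1e-6 * max(np.abs(baseline.H).sum(), 1.0)

    def test_objective_monotone_and_w_rows_unit_norm(self, rng):
        W0 = gaussian_templates(3)
        A = rng.uniform(0.1, 1.0, (30, 3)) @ W0 + rng.uniform(0, 0.01, (30, 80))
        est = MCRALS(n_components=3, random_state=0)
        H = est.fit_transform(A)
        diffs = np.diff(est.objective_history_)
        assert np.all(diffs <= 1e-10 * max(1.0, est.objective_history_[0]))
        norms = np.linalg.norm(est.components_, axis=1)
        np.testing.assert_allclose(norms[norms > 0], 1.0, atol=1e-10)
        # renormalization convention leaves the reconstruction consistent
        recon_err = np.linalg.norm(np.clip(A, 0, None) - H @ est.components_)
        assert recon_err == pytest.approx(est.reconstruction_err_, rel=1e-10)

    def test_rank_one_solution_equals_leading_singular_pair(self, rng):
        u = rng.uniform(0.1, 1.0, 12)
        v = rng.uniform(0.1, 1.0, 30)
        A = np.outer(u, v)
        result = mcr_als(A, n_components=1, alpha_l1_h=0.0, init="random", seed=1)
        U, s, Vt = np.linalg.svd(A)
        cos_w = abs(
            float(np.dot(result.W[0], Vt[0]) / np.linalg.norm(result.W[0]) / np.linalg.norm(Vt[0]))
        )
        cos_h = abs(
            float(
                np.dot(result.H[:, 0], U[:, 0])
                / np.linalg.norm(result.H[:, 0])
                / np.linalg.norm(U[:, 0])
            )
        )
        assert cos_w > 1 - 1e-8 and cos_h > 1 - 1e-8

    def test_all_zero_matrix_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            mcr_als(np.zeros((5, 10)), n_components=2)

    def test_recovers_generator_components_on_small_cohort(self, small_cohort):
        """Six planted biomolecular spectra are resolved from ~200 noisy cells."""
        fp = small_cohort.spectra.crop(600, 1800)
        fp, _ = svd_denoise(fp, n_keep="auto")
        est = MCRALS(n_components=6, alpha_l1_h=5e-05, random_state=0)
        H = est.fit_transform(fp.intensity)
        truth = small_cohort.true_components.crop(600, 1800)
        resolved = ComponentSet(
            axis=fp.axis, spectra=est.components_, names=[f"c{i}" for i in range(6)]
        )
        mapping, _, unmatched = match_components(resolved, truth)
        assert unmatched == []
        assert min(cos for _, cos in mapping.values()) >= 0.95
        idx = {n: i for i, n in enumerate(small_cohort.true_profile.components)}
        for res_name, (ref_name, _) in mapping.items():
            j = int(res_name[1:])
            r = np.corrcoef(H[:, j], small_cohort.true_profile.values[:, idx[ref_name]])[0, 1]
            assert r >= 0.9


class TestMatching:
    def test_identical_sets_identity_mapping(self, rng):
        axis = np.arange(50, dtype=float)
        W = rng.uniform(0, 1, (4, 50))
        cs = ComponentSet(axis=axis, spectra=W, names=["a", "b", "c", "d"])
        mapping, sim, unmatched = match_components(cs, cs)
        assert unmatched == []
        for name, (ref, cos) in mapping.items():
            assert name == ref
            assert cos == pytest.approx(1.0)

    def test_assignment_equals_brute_force_on_3x3(self, rng):
        axis = np.arange(30, dtype=float)
        resolved = ComponentSet(
            axis=axis, spectra=rng.uniform(0, 1, (3, 30)), names=["r0", "r1", "r2"]
        )
        reference = ComponentSet(
            axis=axis, spectra=rng.uniform(0, 1, (3, 30)), names=["f0", "f1", "f2"]
        )
        mapping, sim, _ = match_components(resolved, reference)
        best_perm = max(
            itertools.permutations(range(3)),
            key=lambda p: sum(sim[i, p[i]] for i in range(3)),
        )
        for i, j in enumerate(best_perm):
            assert mapping[f"r{i}"][0] == f"f{j}"

    def test_orthogonal_shuffle_recovered(self):
        axis = np.arange(12, dtype=float)
        W = np.eye(4, 12)
        perm = [2, 0, 3, 1]
        shuffled = ComponentSet(axis=axis, spectra=W[perm], names=["s0", "s1", "s2", "s3"])
        base = ComponentSet(axis=axis, spectra=W, names=["b0", "b1", "b2", "b3"])
        mapping, _, _ = match_components(shuffled, base)
        for i, j in enumerate(perm):
            assert mapping[f"s{i}"][0] == f"b{j}"

    def test_axis_mismatch_raises(self, rng):
        a = ComponentSet(axis=np.arange(10.0), spectra=rng.uniform(0, 1, (2, 10)), names=["x", "y"])
        b = ComponentSet(
            axis=np.arange(10.0) + 5, spectra=rng.uniform(0, 1, (2, 10)), names=["x", "y"]
        )
        with pytest.raises(ValueError, match="axes"):
            match_components(a, b)
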