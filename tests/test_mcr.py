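"""MCR-ALS: fit diagnostics, SIMPLISMA, the trilinearity constraint and
recovery of generator ground truth."""

import itertools
import warnings

import numpy as np
import pytest

import aquadom.mcr as mcr_mod
from aquadom.io_formats import EEMStack, ValidationError
from aquadom.mcr import (
    estimate_rank,
    explained_variance,
    fit_mcr_trilinear,
    lack_of_fit,
    match_components,
    purest_variables,
)
from aquadom.synthetic import (
    SyntheticTruth,
    component_profiles,
    default_component_library,
    simulate_eem_stack,
    standard_grids,
)


def three_component_stack(noise=0.0, seed=5, K=4):
    lib = default_component_library()[:3]
    rng = np.random.default_rng(seed)
    C = rng.uniform(1.0, 8.0, size=(K, 3))
    truth = SyntheticTruth(components=lib, C_true=C, noise_sigma=noise, seed=seed + 1)
    return simulate_eem_stack(truth, add_scatter=False), truth


class TestExplainedVariance:
    def test_perfect_model_scores_100(self):
        D = np.random.default_rng(0).uniform(0, 1, (20, 30))
        assert explained_variance(D, D) == pytest.approx(100.0)

    def test_zero_model_scores_0(self):
        D = np.random.default_rng(0).uniform(0, 1, (20, 30))
        assert explained_variance(D, np.zeros_like(D)) == pytest.approx(0.0)

    def test_one_percent_residual_scores_99(self):
        # construct rss = 1% of tss exactly
        D = np.ones((10, 10))
        Dhat = D - np.sqrt(0.01) * np.ones_like(D)
        assert explained_variance(D, Dhat) == pytest.approx(99.0)

    def test_masked_cells_excluded(self):
        D = np.ones((4, 4))
        Dhat = D.copy()
        Dhat[0, 0] = 100.0
        mask = np.zeros_like(D, dtype=bool)
        mask[0, 0] = True
        assert explained_variance(D, Dhat, mask) == pytest.approx(100.0)

    def test_zero_total_sum_of_squares_rejected(self):
        with pytest.raises(ValidationError):
            explained_variance(np.zeros((3, 3)), np.ones((3, 3)))

    def test_worse_than_zero_model_goes_negative(self):
        D = np.ones((3, 3))
        assert explained_variance(D, 3 * D) < 0


class TestEstimateRank:
    def test_exact_three_component_stack(self):
        stack, _ = three_component_stack()
        assert estimate_rank(stack)[0] == 3

    def test_rank_one_stack(self):
        lib = default_component_library()[:1]
        truth = SyntheticTruth(lib, np.array([[1.0], [2.0], [0.5]]), 0.0, 3)
        assert estimate_rank(simulate_eem_stack(truth, add_scatter=False))[0] == 1

    def test_noise_does_not_inflate_rank(self):
        stack, truth = three_component_stack()
        peak = max(float(e.intensity.max()) for e in stack)
        noisy, _ = three_component_stack(noise=0.01 * peak)
        assert estimate_rank(noisy)[0] == 3

    def test_zero_stack_rejected(self):
        lib = default_component_library()[:1]
        truth = SyntheticTruth(lib, np.zeros((2, 1)), 0.0, 3)
        with pytest.raises(ValidationError):
            estimate_rank(simulate_eem_stack(truth, add_scatter=False))


class TestPurestVariables:
    def brute_force_best_subset(self, D, n):
        """Independent oracle: subset maximizing the determinant of the
        cosine (correlation-around-origin) submatrix."""
        norms = np.linalg.norm(D, axis=0)
        L = D / np.where(norms > 0, norms, 1)
        best, best_det = None, -np.inf
        for subset in itertools.combinations(range(D.shape[1]), n):
            G = L[:, subset].T @ L[:, subset]
            d = np.linalg.det(G)
            if d > best_det:
                best, best_det = subset, d
        return set(best)

    def test_orthogonal_pure_columns_found(self):
        # 6-column toy matrix: columns 0-2 pure (orthogonal), 3-5 mixtures
        D = np.array([
            [1, 0, 0, 1, 0, 1],
            [1, 0, 0, 1, 1, 0],
            [0, 1, 0, 0, 1, 1],
            [0, 1, 0, 1, 1, 0],
            [0, 0, 1, 0, 1, 1],
            [0, 0, 1, 1, 0, 1],
        ], dtype=float)
        selected = set(purest_variables(D, 3))
        assert selected == self.brute_force_best_subset(D, 3) == {0, 1, 2}

    def test_single_pick_takes_dominant_variance_column(self):
        rng = np.random.default_rng(4)
        D = np.abs(rng.normal(1.0, 0.01, (50, 5)))
        D[:25, 2] = 5.0  # high-contrast column
        assert purest_variables(D, 1) == [2]

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        D = rng.uniform(0, 1, (30, 12))
        assert purest_variables(D, 4) == purest_variables(D, 4)

    def test_too_many_requested_rejected(self):
        with pytest.raises(ValidationError):
            purest_variables(np.ones((3, 2)), 3)


class TestFitMCRTrilinear:
    def test_rank_one_stack_recovered_exactly(self):
        lib = default_component_library()[:1]
        scales = np.array([1.0, 2.0, 0.5])
        truth = SyntheticTruth(lib, scales[:, None], 0.0, 3)
        stack = simulate_eem_stack(truth, add_scatter=False)
        res = fit_mcr_trilinear(stack, nc=1)
        assert res.r2 == pytest.approx(100.0, abs=1e-6)
        ratio = res.C[:, 0] / scales
        assert np.allclose(ratio, ratio[0], rtol=1e-8)

    def test_noise_free_three_component_recovery(self):
        stack, truth = three_component_stack(K=6)
        res = fit_mcr_trilinear(stack, nc=3)
        assert res.r2 >= 99.99
        perm, sims = match_components(res, truth)
        assert sorted(perm.tolist()) == [0, 1, 2]
        assert sims.min() >= 0.999

    def test_factors_nonnegative_and_normalized(self):
        stack, _ = three_component_stack(noise=0.05)
        res = fit_mcr_trilinear(stack, nc=3)
        assert (res.S_ex >= 0).all() and (res.S_em >= 0).all() and (res.C >= 0).all()
        assert np.allclose(res.S_ex.max(axis=0), 1.0)
        assert np.allclose(res.S_em.max(axis=1), 1.0)
        # components sorted by descending total contribution
        totals = res.C.sum(axis=0)
        assert np.all(np.diff(totals) <= 1e-12)

    def test_unconstrained_lack_of_fit_monotone(self):
        stack, _ = three_component_stack(noise=0.05, K=5)
        res = fit_mcr_trilinear(
            stack, nc=3, apply_trilinearity=False, init="simplisma"
        )
        lof = 100.0 * np.sqrt(1.0 - np.asarray(res.history) / 100.0)
        assert np.all(np.diff(lof) <= 1e-10 * np.maximum(lof[:-1], 1e-30))

    def test_refolded_blocks_rank_one_at_exit(self):
        stack, _ = three_component_stack(noise=0.05, K=5)
        res = fit_mcr_trilinear(stack, nc=3)
        A = np.vstack([res.S_ex @ np.diag(res.C[k]) for k in range(len(stack))])
        for c in range(3):
            sv = np.linalg.svd(
                mcr_mod._refold(A[:, c], 45, len(stack)), compute_uv=False
            )
            assert sv[1] <= 1e-8 * sv[0]

    def test_constraint_costs_little_fit_on_trilinear_data(self):
        stack, _ = three_component_stack(noise=0.05, K=5)
        tri = fit_mcr_trilinear(stack, nc=3)
        unc = fit_mcr_trilinear(stack, nc=3, apply_trilinearity=False)
        assert abs(unc.r2 - tri.r2) <= 0.5

    def test_initializations_agree_on_noise_free_data(self):
        stack, _ = three_component_stack(K=6)
        a = fit_mcr_trilinear(stack, nc=3, init="simplisma")
        b = fit_mcr_trilinear(stack, nc=3, init="simplisma_cols")
        # same subspace up to permutation/scale: principal angles ~ 0
        qa, _ = np.linalg.qr(a.S_em.T)
        qb, _ = np.linalg.qr(b.S_em.T)
        angles = np.arccos(np.clip(np.linalg.svd(qa.T @ qb, compute_uv=False), -1, 1))
        assert angles.max() <= 1e-3

    def test_masked_cells_excluded_from_fit(self):
        stack, truth = three_component_stack(K=4)
        # corrupt one region but mask it: fit should be unaffected
        bad = stack[0].copy()
        bad.intensity[:, 150:160] = 50.0
        bad.mask = np.zeros_like(bad.intensity, dtype=bool)
        bad.mask[:, 150:160] = True
        stack2 = EEMStack([bad] + [e.copy() for e in stack[1:]])
        res = fit_mcr_trilinear(stack2, nc=3)
        assert res.r2 >= 99.9

    def test_nc_out_of_range_rejected(self):
        stack, _ = three_component_stack()
        with pytest.raises(ValidationError):
            fit_mcr_trilinear(stack, nc=0)
        with pytest.raises(ValidationError):
            fit_mcr_trilinear(stack, nc=400)

    def test_non_convergence_warns(self):
        stack, _ = three_component_stack(noise=0.05, K=5)
        with pytest.warns(UserWarning, match="did not converge"):
            res = fit_mcr_trilinear(stack, nc=3, max_iter=2, init="simplisma")
        assert res.converged is False


class TestMatchComponents:
    def _result_from_truth(self, truth, order):
        ex, em = standard_grids()
        S_ex, S_em = component_profiles(truth.components, ex, em)
        from aquadom.mcr import MCRResult

        return MCRResult(
            S_ex=S_ex[:, order], S_em=S_em[order, :],
            C=truth.C_true[:, order], r2=100.0, lof=0.0, n_iter=1,
            converged=True, history=[100.0], ex_grid=ex, em_grid=em,
            sample_ids=[f"S{k}" for k in range(truth.C_true.shape[0])],
        )

    def test_identity_match(self):
        _, truth = three_component_stack()
        res = self._result_from_truth(truth, [0, 1, 2])
        perm, sims = match_components(res, truth)
        assert perm.tolist() == [0, 1, 2]
        assert np.allclose(sims, 1.0)

    def test_swapped_components_recovered(self):
        _, truth = three_component_stack()
        res = self._result_from_truth(truth, [2, 0, 1])
        perm, sims = match_components(res, truth)
        assert perm.tolist() == [2, 0, 1]
        assert np.allclose(sims, 1.0)

    def test_count_mismatch_rejected(self):
        _, truth = three_component_stack()
        res = self._result_from_truth(truth, [0, 1, 2])
        truth_bigger = SyntheticTruth(
            default_component_library(), np.ones((4, 6)), 0.0, 0
        )
        with pytest.raises(ValidationError):
            match_components(res, truth_bigger)
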