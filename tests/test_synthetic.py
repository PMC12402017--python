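"""The campaign generator obeys its own ground truth."""

import warnings

import numpy as np
import pytest

from aquadom.io_formats import ValidationError
from aquadom.mcr import explained_variance
from aquadom.synthetic import (
    CircuitParams,
    ComponentSpec,
    SyntheticTruth,
    component_profiles,
    default_component_library,
    gaussian_profile,
    raman_emission,
    simulate_campaign,
    simulate_eem_stack,
    simulate_eis,
    simulate_scatter_ridges,
    standard_grids,
)
from conftest import make_eem


class TestGaussianProfile:
    def test_peaks_at_center_with_value_one(self):
        ex, _ = standard_grids()
        prof = gaussian_profile(340.0, 25.0, ex)
        assert ex[np.argmax(prof)] == 340.0
        assert prof[np.argmax(prof)] == 1.0

    def test_symmetric_about_center(self):
        ex, _ = standard_grids()
        prof = gaussian_profile(340.0, 25.0, ex)
        i = int(np.flatnonzero(ex == 340.0)[0])
        assert prof[i + 2] == pytest.approx(prof[i - 2], abs=1e-12)

    def test_center_outside_grid_warns_but_returns(self):
        ex, _ = standard_grids()
        with pytest.warns(UserWarning, match="outside"):
            prof = gaussian_profile(200.0, 10.0, ex)
        assert prof.max() == 1.0


class TestComponentLibrary:
    def test_six_components_at_canonical_positions(self):
        lib = default_component_library()
        assert len(lib) == 6
        assert [c.name for c in lib] == [f"C{i}" for i in range(1, 7)]
        assert lib[0].ex_center == 340.0 and lib[0].em_center == 474.0
        assert lib[5].em_center == 294.0

    def test_all_stokes_shifts_positive(self):
        assert all(c.stokes_shift > 0 for c in default_component_library())

    def test_negative_stokes_shift_rejected(self):
        with pytest.raises(ValidationError, match="Stokes"):
            ComponentSpec("bad", 400.0, 20.0, 350.0, 30.0)

    def test_shoulders_sit_below_260(self):
        for c in default_component_library():
            assert c.secondary_ex_center < 260.0


class TestScatterRidges:
    def test_first_order_ridge_on_diagonal(self):
        eem = make_eem(0.0)
        out = simulate_scatter_ridges(eem)
        assert out.intensity[out.ex_index(300), out.em_index(300)] > 0

    def test_raman_ridge_position_for_ex_350(self):
        # 1/em = 1/350 - 3400e-7 => em = 1/2.517143e-3 ~ 397.28 nm
        assert raman_emission(350.0) == pytest.approx(397.276, abs=0.01)
        eem = make_eem(0.0)
        out = simulate_scatter_ridges(eem, rayleigh1_amplitude=0.0,
                                      rayleigh2_amplitude=0.0, raman_amplitude=1.0)
        row = out.intensity[out.ex_index(350)]
        assert out.em_grid[np.argmax(row)] == pytest.approx(397.0, abs=1.0)

    def test_second_order_ridge_at_twice_excitation(self):
        eem = make_eem(0.0)
        out = simulate_scatter_ridges(eem, rayleigh1_amplitude=0.0,
                                      raman_amplitude=0.0, rayleigh2_amplitude=1.0)
        row = out.intensity[out.ex_index(260)]
        assert out.em_grid[np.argmax(row)] == 520.0


def _three_component_truth(noise=0.0, seed=5):
    lib = default_component_library()[:3]
    C = np.array([[1, 2, 3], [4, 5, 6], [2, 1, 0.5], [1, 1, 1]], float)
    return SyntheticTruth(components=lib, C_true=C, noise_sigma=noise, seed=seed)


class TestEEMStackGenerator:
    def test_shapes_and_nonnegativity(self):
        truth = _three_component_truth()
        stack = simulate_eem_stack(truth, add_scatter=True)
        assert len(stack) == 4
        assert stack[0].shape == (45, 301)
        assert all((e.intensity >= 0).all() for e in stack)

    def test_noise_free_stack_is_exactly_trilinear(self):
        truth = _three_component_truth()
        stack = simulate_eem_stack(truth, add_scatter=False)
        ex, em = standard_grids()
        S_ex, S_em = component_profiles(truth.components, ex, em)
        for k, eem in enumerate(stack):
            model = S_ex @ np.diag(truth.C_true[k]) @ S_em
            assert explained_variance(eem.intensity, model) == pytest.approx(100.0)

    def test_same_seed_bitwise_identical(self):
        truth = _three_component_truth(noise=0.1)
        a = simulate_eem_stack(truth)
        b = simulate_eem_stack(truth)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.intensity, eb.intensity)

    def test_different_seeds_differ(self):
        t1 = _three_component_truth(noise=0.1, seed=5)
        t2 = _three_component_truth(noise=0.1, seed=6)
        assert not np.array_equal(
            simulate_eem_stack(t1)[0].intensity, simulate_eem_stack(t2)[0].intensity
        )

    def test_component_count_mismatch_rejected(self):
        lib = default_component_library()[:3]
        with pytest.raises(ValidationError):
            SyntheticTruth(components=lib, C_true=np.ones((4, 2)), noise_sigma=0, seed=0)


class TestEISGenerator:
    def test_default_grid_has_500_points(self):
        spec = simulate_eis(CircuitParams(R_s=1e3, R_ct=1e5, tau=1e-3, alpha=0.9))
        assert spec.freq_grid.size == 500
        assert spec.freq_grid[0] == pytest.approx(0.1)
        assert spec.freq_grid[-1] == pytest.approx(20000.0)

    def test_phase_bounded_in_capacitive_quadrant(self):
        spec = simulate_eis(CircuitParams(R_s=1e3, R_ct=1e5, tau=1e-3, alpha=0.9))
        assert (spec.phase <= 1e-12).all() and (spec.phase >= -90).all()

    def test_pure_resistor_limit_has_zero_phase(self):
        spec = simulate_eis(CircuitParams(R_s=1e3, R_ct=1e-9, tau=1e-3, alpha=0.9))
        assert np.allclose(spec.phase, 0.0, atol=1e-9)

    def test_matches_direct_complex_arithmetic(self):
        p = CircuitParams(R_s=2e3, R_ct=5e4, tau=2e-3, alpha=0.85)
        f = 37.0
        spec = simulate_eis(p, freq_grid=np.array([f]))
        w = 2 * np.pi * f
        Z = p.R_s + p.R_ct / (1 + (1j * w * p.tau) ** p.alpha)
        assert spec.phase[0] == pytest.approx(np.degrees(np.arctan2(Z.imag, Z.real)), abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            CircuitParams(R_s=-1, R_ct=1, tau=1, alpha=0.5)
        with pytest.raises(ValidationError):
            CircuitParams(R_s=1, R_ct=1, tau=1, alpha=1.5)


class TestCampaign:
    def test_blank_contributions_are_zero(self, campaign):
        assert np.all(campaign.truth.C_true[-1] == 0)
        assert campaign.stack.sample_ids[-1] == "DOMfree"

    def test_uv254_rank_order_follows_dom_gradient(self, campaign):
        uv254 = [
            float(np.interp(254.0, u.wl_grid, u.absorbance)) for u in campaign.uv
        ]
        loads = np.concatenate([np.linspace(0.1, 1.0, 9), [0.0]])
        assert list(np.argsort(uv254)) == list(np.argsort(loads, kind="stable"))

    def test_conductivity_monotone_in_dom_load(self, campaign):
        cond = campaign.sample_table["conductivity_us"].to_numpy()
        assert cond[-1] == cond.min()              # blank
        assert np.all(np.diff(cond[:-1]) > 0)      # R1..R9 along the gradient

    def test_eis_design_five_samples_two_replicates(self, campaign):
        assert len(campaign.eis) == 10
        assert len(campaign.eis_sample_ids) == 5
        assert campaign.eis_sample_ids == ["DOMfree", "R3", "R5", "R6", "R9"]
        for sid in campaign.eis_sample_ids:
            reps = sorted(s.replicate for s in campaign.eis if s.sample_id == sid)
            assert reps == [1, 2]

    def test_campaign_is_seed_deterministic(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = simulate_campaign(seed=3)
            b = simulate_campaign(seed=3)
        assert np.array_equal(a.truth.C_true, b.truth.C_true)
        assert np.array_equal(a.stack[0].intensity, b.stack[0].intensity)
        assert np.array_equal(a.eis[0].phase, b.eis[0].phase)
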