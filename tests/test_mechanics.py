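"""Stretching work, sensing free energy and the CHAOS parameter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chaoscalc import units
from chaoscalc.mechanics import (
    HookeanStretchModel,
    SensingModel,
    StretchCurve,
    chaos_invariance_profile,
    chaos_parameter,
    fit_area_compressibility,
    relative_strain,
    sensing_free_energy,
    stretch_work,
    stretch_work_multipoint,
)
from chaoscalc.synthetic import generate_stretch_curves

from conftest import exact_estimate


class TestRelativeStrain:
    def test_production_protocol_strain_is_16_5_percent(self):
        assert relative_strain(49.4, 42.4) == pytest.approx(0.165, abs=5e-4)

    def test_reference_area_has_zero_strain(self):
        assert relative_strain(42.4, 42.4) == 0.0

    def test_doubled_area(self):
        assert relative_strain(84.8, 42.4) == pytest.approx(1.0)

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError):
            relative_strain(40.0, 0.0)


class TestStretchCurve:
    def test_requires_first_point_at_reference_area(self):
        with pytest.raises(ValueError, match="reference area"):
            StretchCurve.from_arrays([43.0, 49.4], [1.0, 20.0], area0=42.4)

    def test_rejects_duplicate_areas(self):
        with pytest.raises(ValueError):
            StretchCurve.from_arrays([42.4, 42.4], [0.0, 1.0])

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            StretchCurve.from_arrays([42.4], [0.0])


class TestAreaCompressibilityFit:
    def test_two_point_exact_line(self):
        curve = StretchCurve.from_arrays([42.4, 46.64], [0.0, 30.0])
        fit = fit_area_compressibility(curve)
        assert fit.k_a == pytest.approx(300.0)

    def test_noiseless_synthetic_curve_recovers_modulus(
        self, noiseless_reference, noiseless_peptide
    ):
        ref, _ = generate_stretch_curves(
            noiseless_reference, noiseless_peptide, n_frames=10, seed=0
        )
        fit = fit_area_compressibility(ref)
        assert fit.k_a == pytest.approx(240.0, abs=1e-9)

    def test_noisy_synthetic_curve_recovers_within_two_se(
        self, noisy_reference, noisy_peptide
    ):
        ref, _ = generate_stretch_curves(
            noisy_reference, noisy_peptide, n_frames=4000, seed=7
        )
        fit = fit_area_compressibility(ref)
        assert abs(fit.k_a - 240.0) < 2 * fit.k_a_err

    def test_model_wrapper_matches_function(self):
        curve = StretchCurve.from_arrays([42.4, 49.4], [0.0, 20.0])
        model = HookeanStretchModel(curve)
        assert model.fit().k_a == pytest.approx(20.0 / relative_strain(49.4, 42.4))
        assert "K_A" in model.fit().summary()


class TestStretchWork:
    def test_zero_tensions_give_zero_work(self):
        w = stretch_work(exact_estimate(0, 42.4), exact_estimate(0, 49.4), 42.4, 49.4)
        assert w.value == 0.0

    def test_hand_trapezoid_with_unit_conversion(self):
        w = stretch_work(exact_estimate(0, 42.4), exact_estimate(20, 49.4), 42.4, 49.4)
        # (0+20)/2 * 7 = 70 mN/m nm^2 = 42.2 kJ/mol
        assert w.value == pytest.approx(42.2, abs=0.05)

    def test_swapping_end_states_negates(self):
        s0, sA = exact_estimate(3.0, 42.4), exact_estimate(20.0, 49.4)
        forward = stretch_work(s0, sA, 42.4, 49.4)
        backward = stretch_work(sA, s0, 49.4, 42.4)
        assert backward.value == pytest.approx(-forward.value)

    def test_coincident_end_states_error(self):
        with pytest.raises(ValueError):
            stretch_work(exact_estimate(0, 42.4), exact_estimate(0, 42.4), 42.4, 42.4)


class TestStretchWorkMultipoint:
    def test_exact_on_linear_curves(self):
        areas = np.linspace(42.4, 49.4, 6)
        sig = 240.0 * (areas - 42.4) / 42.4
        curve = StretchCurve.from_arrays(areas, sig)
        multi = stretch_work_multipoint(curve)
        ends = stretch_work(
            curve.points[0].tension, curve.points[-1].tension, 42.4, 49.4
        )
        assert multi.value == pytest.approx(ends.value, rel=1e-12)

    def test_quadratic_curve_within_trapezoid_error_bound(self):
        a0, a1 = 42.4, 49.4
        areas = np.linspace(a0, a1, 6)
        sig = (areas - a0) ** 2  # integral = (a1-a0)^3/3 mN/m nm^2
        curve = StretchCurve.from_arrays(areas, sig)
        exact = units.mech_work_to_kj_per_mol((a1 - a0) ** 3 / 3)
        h = areas[1] - areas[0]
        bound = units.mech_work_to_kj_per_mol((a1 - a0) * h**2 / 12 * 2)  # f''=2
        assert abs(stretch_work_multipoint(curve).value - exact) <= bound + 1e-12

    def test_single_interval_equals_end_state_work(self):
        curve = StretchCurve.from_arrays([42.4, 49.4], [1.0, 17.0])
        multi = stretch_work_multipoint(curve)
        ends = stretch_work(curve.points[0].tension, curve.points[-1].tension, 42.4, 49.4)
        assert multi.value == pytest.approx(ends.value)


def _random_curve_pair(rng, n_points=6):
    a0 = rng.uniform(30, 60)
    areas = a0 + np.sort(np.concatenate([[0], rng.uniform(0.5, 10, n_points - 1)]))
    ref = StretchCurve.from_arrays(areas, rng.normal(0, 30, n_points), label="ref")
    pep = StretchCurve.from_arrays(areas, rng.normal(0, 30, n_points), label="pep")
    return ref, pep


class TestSensingFreeEnergy:
    def test_identical_curves_give_zero(self):
        curve = StretchCurve.from_arrays([42.4, 49.4], [0.0, 20.0])
        res = sensing_free_energy(curve, curve)
        assert res.ddF == 0.0

    def test_hand_evaluated_four_tension_formula(self):
        ref = StretchCurve.from_arrays([42.4, 49.4], [0.0, 20.0])
        pep = StretchCurve.from_arrays([42.4, 49.4], [-2.0, 12.0])
        res = sensing_free_energy(pep, ref)
        # 3.5 * ((12 - 2) - (20 + 0)) = -35 mN/m nm^2 = -21.1 kJ/mol
        assert res.ddF == pytest.approx(-21.1, abs=0.05)
        assert res.is_sensor

    def test_equals_difference_of_stretch_works(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            ref, pep = _random_curve_pair(rng)
            res = sensing_free_energy(pep, ref, mode="end_state")
            wp = stretch_work(
                pep.points[0].tension, pep.points[-1].tension, pep.area0, pep.areas[-1]
            )
            wr = stretch_work(
                ref.points[0].tension, ref.points[-1].tension, ref.area0, ref.areas[-1]
            )
            assert res.ddF == pytest.approx(wp.value - wr.value, rel=1e-12, abs=1e-12)

    def test_mismatched_reference_area_rejected(self):
        ref = StretchCurve.from_arrays([42.4, 49.4], [0.0, 20.0])
        pep = StretchCurve.from_arrays([43.0, 49.4], [0.0, 12.0])
        with pytest.raises(ValueError, match="A0"):
            sensing_free_energy(pep, ref)

    def test_multipoint_needs_matching_grids(self):
        ref = StretchCurve.from_arrays([42.4, 45.0, 49.4], [0.0, 9.0, 20.0])
        pep = StretchCurve.from_arrays([42.4, 46.0, 49.4], [0.0, 8.0, 12.0])
        with pytest.raises(ValueError, match="grid"):
            sensing_free_energy(pep, ref, mode="multi_point")


class TestChaosParameter:
    def test_zero_sensing_gives_zero_chaos(self):
        ref = StretchCurve.from_arrays([42.4, 49.4], [0.0, 20.0])
        res = sensing_free_energy(ref, ref)
        assert res.chaos == 0.0

    def test_hand_unit_conversion(self):
        ref = StretchCurve.from_arrays([42.4, 49.4], [0.0, 20.0])
        pep = StretchCurve.from_arrays([42.4, 49.4], [-2.0, 12.0])
        res = sensing_free_energy(pep, ref)
        # -21.1 kJ/mol over -20 mN/m = -12.04 kJ/mol/nm^2 -> 1.75 nm^2
        assert res.delta_sigma == pytest.approx(-20.0)
        assert res.chaos == pytest.approx(1.75, abs=0.005)
        explicit = chaos_parameter(
            res, ref.points[0].tension, ref.points[-1].tension
        )
        assert explicit.value == pytest.approx(res.chaos)

    def test_pure_area_shift_chaos_equals_injected_area(
        self, noiseless_reference, noiseless_peptide
    ):
        from dataclasses import replace

        pure = replace(noiseless_peptide, softening=1.0)
        ref, pep = generate_stretch_curves(noiseless_reference, pure, n_frames=10, seed=0)
        res = sensing_free_energy(pep, ref)
        assert res.chaos == pytest.approx(0.5, abs=1e-10)

    def test_degenerate_tension_difference_errors(self):
        ref = StretchCurve.from_arrays([42.4, 49.4], [5.0, 5.0])
        pep = StretchCurve.from_arrays([42.4, 49.4], [1.0, 2.0])
        with pytest.raises(ZeroDivisionError):
            sensing_free_energy(pep, ref)


class TestChaosInvariance:
    def test_pure_shift_profile_is_flat_to_machine_precision(
        self, noiseless_reference, noiseless_peptide
    ):
        from dataclasses import replace

        pure = replace(noiseless_peptide, softening=1.0)
        ref, pep = generate_stretch_curves(noiseless_reference, pure, n_frames=10, seed=0)
        profile, spread = chaos_invariance_profile(pep, ref)
        values = [p.chaos for p in profile]
        assert np.allclose(values, 0.5, atol=1e-10)
        assert spread < 1e-9

    def test_softening_deviation_matches_closed_form(
        self, noiseless_reference, noiseless_peptide
    ):
        ref, pep = generate_stretch_curves(
            noiseless_reference, noiseless_peptide, n_frames=10, seed=0
        )
        profile, _ = chaos_invariance_profile(pep, ref)
        s, dap = noiseless_peptide.softening, noiseless_peptide.dA_p
        for point in profile:
            da = point.end_area - noiseless_reference.A0
            assert point.chaos == pytest.approx((1 - s) * da / 2 + s * dap, abs=1e-10)

    def test_reference_against_itself_gives_zeros(self, noiseless_reference):
        ref, _ = generate_stretch_curves(
            noiseless_reference, noiseless_reference, n_frames=10, seed=0
        )
        profile, _ = chaos_invariance_profile(ref, ref)
        assert np.allclose([p.chaos for p in profile], 0.0)


class TestUnits:
    @given(x=st.floats(-1e4, 1e4))
    @settings(deadline=None)
    def test_round_trips_invert_to_machine_precision(self, x):
        assert units.mn_per_m_to_bar_nm(units.bar_nm_to_mn_per_m(x)) == pytest.approx(
            x, rel=1e-14, abs=1e-12
        )
        back = units.tension_to_energy_density(x) / units.MN_PER_M_TO_KJ_PER_MOL_NM2
        assert back == pytest.approx(x, rel=1e-14, abs=1e-12)


class TestModelObjects:
    def test_sensing_model_fit_matches_function(self):
        ref = StretchCurve.from_arrays([42.4, 49.4], [0.0, 20.0], label="reference")
        pep = StretchCurve.from_arrays([42.4, 49.4], [-2.0, 12.0], label="toy")
        res = SensingModel(ref, pep).fit()
        assert res.ddF == sensing_free_energy(pep, ref).ddF
        text = res.summary()
        assert "CHAOS" in text and "kJ/mol" in text and "toy" in text


def test_sensing_model_plot_returns_axes():
    ref = StretchCurve.from_arrays([42.4, 49.4], [0.0, 20.0], label="reference")
    pep = StretchCurve.from_arrays([42.4, 49.4], [-2.0, 12.0], label="toy")
    ax = SensingModel(ref, pep).plot()
    assert ax.get_ylabel() == "surface tension (mN/m)"
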