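"""Surface tension from pressure tensors: definitions, trimming, blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chaoscalc.synthetic import HookeanMembraneModel, model_tension, simulate_pressure_trace
from chaoscalc.tension import (
    TensionSeries,
    binding_trace,
    block_average,
    combine_replicas,
    equilibration_trim,
    estimate_tension,
    surface_tension_series,
)

from conftest import exact_estimate, make_trace


class TestSurfaceTensionSeries:
    def test_isotropic_pressure_gives_zero_tension(self):
        trace = make_trace([1.0, 1.0], 1.0, 1.0, lz=7.3)
        assert np.allclose(surface_tension_series(trace).bar_nm, 0.0)

    @pytest.mark.parametrize(
        "lz,pzz,plat,expected_bar_nm,expected_mn_per_m",
        [(10.0, 1.0, -99.0, 1000.0, 100.0), (5.0, 2.0, -2.0, 20.0, 2.0)],
    )
    def test_hand_evaluated_tensions(self, lz, pzz, plat, expected_bar_nm, expected_mn_per_m):
        trace = make_trace([plat], plat, pzz, lz=lz)
        series = surface_tension_series(trace)
        assert series.bar_nm[0] == pytest.approx(expected_bar_nm)
        assert series.mn_per_m[0] == pytest.approx(expected_mn_per_m)

    @given(
        pxx=st.floats(-500, 500),
        pyy=st.floats(-500, 500),
        pzz=st.floats(-500, 500),
        lz=st.floats(0.1, 50),
    )
    @settings(deadline=None)
    def test_symmetric_in_lateral_components_and_linear_in_lz(self, pxx, pyy, pzz, lz):
        a = surface_tension_series(make_trace([pxx], pyy, pzz, lz=lz)).bar_nm[0]
        b = surface_tension_series(make_trace([pyy], pxx, pzz, lz=lz)).bar_nm[0]
        assert a == pytest.approx(b, abs=1e-9)
        doubled = surface_tension_series(make_trace([pxx], pyy, pzz, lz=2 * lz)).bar_nm[0]
        assert doubled == pytest.approx(2 * a, rel=1e-12, abs=1e-9)

    def test_surften_column_passthrough_matches_recompute(self):
        model = HookeanMembraneModel(noise_amp=20.0)
        trace = simulate_pressure_trace(model, 46.0, 500, seed=3)
        rec = surface_tension_series(trace, source="recompute")
        col = surface_tension_series(trace, source="surften_column")
        assert np.allclose(rec.bar_nm, col.bar_nm)


class TestEquilibrationTrim:
    def test_zero_discard_is_identity(self):
        s = TensionSeries(time=np.array([0.0, 10.0]), bar_nm=np.array([1.0, 2.0]))
        out = equilibration_trim(s, 0.0)
        assert np.array_equal(out.time, s.time)

    def test_boundary_frame_is_kept(self):
        t = np.arange(0.0, 100_001.0, 1000.0)
        s = TensionSeries(time=t, bar_nm=np.zeros_like(t))
        out = equilibration_trim(s, 50_000.0)
        assert out.time[0] == 50_000.0

    def test_discard_beyond_last_frame_errors(self):
        s = TensionSeries(time=np.array([0.0, 10.0]), bar_nm=np.zeros(2))
        with pytest.raises(ValueError, match="leaves no frames"):
            equilibration_trim(s, 11.0)


class TestBlockAverage:
    def test_constant_series(self):
        mean, sem = block_average(np.full(20, 4.2), 5)
        assert mean == pytest.approx(4.2)
        assert sem == 0.0

    def test_hand_arithmetic_two_blocks(self):
        mean, sem = block_average([1.0, 2.0, 3.0, 4.0], 2)
        assert mean == pytest.approx(2.5)
        assert sem == pytest.approx(1.0)

    def test_remainder_dropped_from_front(self):
        # 5 frames, 2 blocks: the leading frame (least equilibrated) is dropped
        mean, _ = block_average([100.0, 1.0, 2.0, 3.0, 4.0], 2)
        assert mean == pytest.approx(2.5)

    def test_matches_plain_mean_when_blocks_divide_length(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        mean, _ = block_average(x, 5)
        assert mean == pytest.approx(x.mean())

    def test_single_block_has_zero_sem(self):
        _, sem = block_average([1.0, 5.0], 1)
        assert sem == 0.0

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            block_average([1.0], 2)


class TestEstimateTension:
    def test_noiseless_trace_recovers_model_tension_exactly(self):
        model = HookeanMembraneModel(noise_amp=0.0)
        area = model.A0 * 1.1
        trace = simulate_pressure_trace(model, area, 100, seed=0)
        est = estimate_tension(trace, n_blocks=5)
        assert est.sigma == pytest.approx(model_tension(model, area), abs=1e-10)
        assert est.sem == 0.0
        assert est.area == area

    def test_surften_source_equals_recompute(self):
        model = HookeanMembraneModel(noise_amp=30.0)
        trace = simulate_pressure_trace(model, 45.0, 1000, seed=5)
        a = estimate_tension(trace, n_blocks=5, source="recompute")
        b = estimate_tension(trace, n_blocks=5, source="surften_column")
        assert a.sigma == pytest.approx(b.sigma, abs=1e-12)
        assert a.sem == pytest.approx(b.sem, abs=1e-12)

    def test_noisy_ar1_trace_recovers_truth_within_three_sem(self):
        model = HookeanMembraneModel(noise_amp=50.0)
        area = model.A0 * 1.1  # model tension 24 mN/m
        trace = simulate_pressure_trace(model, area, 100_000, seed=7)
        est = estimate_tension(trace, n_blocks=5)
        assert abs(est.sigma - 24.0) < 3 * est.sem

    def test_sem_shrinks_with_trace_length_on_average(self):
        model = HookeanMembraneModel(noise_amp=50.0)
        short, long_ = [], []
        for seed in range(10):
            short.append(
                estimate_tension(simulate_pressure_trace(model, 46.0, 2_000, seed=seed)).sem
            )
            long_.append(
                estimate_tension(
                    simulate_pressure_trace(model, 46.0, 32_000, seed=100 + seed)
                ).sem
            )
        assert np.mean(long_) < np.mean(short)

    def test_replica_combination(self):
        a = exact_estimate(10.0, 46.0)
        b = exact_estimate(14.0, 46.0)
        combo = combine_replicas([a, b])
        assert combo.sigma == pytest.approx(12.0)
        assert combo.sem == pytest.approx(np.std([10.0, 14.0], ddof=1) / np.sqrt(2))


class TestBindingTrace:
    def test_constant_distance(self):
        t = np.arange(0.0, 10_000.0, 100.0)
        bt = binding_trace(t, np.full(t.size, 1.5 - 1e-9), window=1000.0)
        assert np.allclose(bt.abs_z, 1.5)
        assert bt.fraction_bound == 1.0
        assert bt.classification == "bound"

    def test_absolute_value_taken_before_averaging(self):
        # sign flips from periodic crossings must not cancel
        t = np.arange(0.0, 1000.0, 10.0)
        z = np.where(np.arange(t.size) % 2 == 0, 2.0, -2.0)
        bt = binding_trace(t, z, window=100.0)
        assert np.allclose(bt.abs_z, 2.0)

    def test_full_span_window_gives_single_mean_value(self):
        t = np.arange(0.0, 100.0, 10.0)
        z = np.linspace(0.5, 2.0, t.size)
        bt = binding_trace(t, z, window=t[-1] - t[0] + 10.0)
        assert bt.abs_z.size == 1
        assert bt.abs_z[0] == pytest.approx(np.mean(np.abs(z)))

    def test_oversized_window_errors(self):
        t = np.arange(0.0, 100.0, 10.0)
        with pytest.raises(ValueError, match="window"):
            binding_trace(t, np.zeros(t.size), window=1e6)

    def test_classification_cutoffs(self):
        t = np.arange(0.0, 1000.0, 10.0)
        z = np.where(np.arange(t.size) < 60, 0.5, 3.0)  # 60% bound
        bt = binding_trace(t, z, window=100.0)
        assert bt.classification == "partial"
        z = np.full(t.size, 5.0)
        assert binding_trace(t, z, window=100.0).classification == "unbound"
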