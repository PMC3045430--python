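"""Core kinetics: forward solution, bisection inversion, temperature, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrnaturnover.kinetics_core import (
    DEFAULT_GRID,
    GeneKinetics,
    KineticsError,
    TimeGrid,
    apply_tr_correction,
    classify_stability,
    decay_profile,
    forward_ra,
    global_summaries,
    solve_kd_interval,
    steady_state_kd,
    temperature_factor,
    theoretical_ra,
)

from conftest import rk4_forward


class TestTimeGrid:
    def test_default_design(self):
        assert DEFAULT_GRID.times == (0, 4, 11, 16, 26, 40)
        assert DEFAULT_GRID.midpoints.tolist() == [2.0, 7.5, 13.5, 21.0, 33.0]

    @pytest.mark.parametrize(
        "times", [(0, 4), (1, 4, 11), (0, 4, 4, 11), (0, 11, 4, 16)]
    )
    def test_invalid_grids_rejected(self, times):
        with pytest.raises(KineticsError):
            TimeGrid(times)


class TestSteadyStateKd:
    def test_ratio_by_definition(self):
        assert steady_state_kd(2.0, 20.0) == pytest.approx(0.1)

    def test_zero_tr_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert steady_state_kd(0.0, 5.0) == 0.0

    def test_nonpositive_ra_is_error(self):
        with pytest.raises(KineticsError):
            steady_state_kd(1.0, 0.0)


class TestForwardRa:
    def test_zero_decay_is_trapezoid(self):
        assert forward_ra(10, 2, 4, 0.0, 5) == pytest.approx(25.0)

    def test_steady_state_fixed_point(self):
        assert forward_ra(10, 1, 1, 0.1, 7) == pytest.approx(10.0)

    def test_matches_rk4_oracle_on_random_draws(self):
        rng = np.random.default_rng(7)
        n = 1000
        ra1 = rng.uniform(0.1, 100, n)
        tr1 = rng.uniform(0, 10, n)
        tr2 = rng.uniform(0, 10, n)
        kd = rng.uniform(0, 1, n)
        dt = rng.uniform(1, 20, n)
        expected = rk4_forward(ra1, tr1, tr2, kd, dt)
        got = np.array([forward_ra(*args) for args in zip(ra1, tr1, tr2, kd, dt)])
        assert np.max(np.abs(got - expected) / np.abs(expected)) < 1e-6

    def test_continuous_at_zero_decay(self):
        a = forward_ra(10, 1, 2, 1e-12, 5)
        b = forward_ra(10, 1, 2, 0.0, 5)
        assert abs(a - b) / b < 1e-8

    def test_strictly_decreasing_in_kd(self):
        kds = np.linspace(0, 2, 200)
        vals = [forward_ra(10, 1, 3, k, 8) for k in kds]
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("bad", [{"dt": -1}, {"kd": -0.1}, {"ra1": math.nan}])
    def test_invalid_inputs_rejected(self, bad):
        args = {"ra1": 10.0, "tr1": 1.0, "tr2": 2.0, "kd": 0.1, "dt": 5.0}
        args.update(bad)
        with pytest.raises(KineticsError):
            forward_ra(**args)


class TestSolveKdInterval:
    def test_zero_decay_bound_flagged(self):
        r = solve_kd_interval(10, 25, 2, 4, 5)
        assert r.kd == 0.0 and r.flag == "at_zero_bound"

    def test_unreachable_ra_flagged(self):
        r = solve_kd_interval(10, 30, 2, 4, 5)
        assert r.kd == 0.0 and r.flag == "no_positive_root"

    def test_steady_state_inversion(self):
        r = solve_kd_interval(10, 10, 1, 1, 7)
        assert r.kd == pytest.approx(0.1, rel=1e-6)
        assert r.flag == "ok"

    def test_round_trip_through_forward(self):
        ra2 = forward_ra(8, 3, 1, 0.2, 5)
        r = solve_kd_interval(8, ra2, 3, 1, 5)
        assert r.kd == pytest.approx(0.2, abs=1e-6)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        kd=st.floats(1e-4, 1.0),
        ra1=st.floats(0.5, 50),
        tr1=st.floats(0.0, 10),
        tr2=st.floats(0.0, 10),
        dt=st.floats(1.0, 20),
    )
    def test_inversion_identity_property(self, kd, ra1, tr1, tr2, dt):
        """solve(forward(kd)) == kd across the physical parameter range."""
        ra2 = forward_ra(ra1, tr1, tr2, kd, dt)
        r = solve_kd_interval(ra1, ra2, tr1, tr2, dt)
        assert r.kd == pytest.approx(kd, rel=1e-6, abs=1e-10)


class TestDecayProfile:
    def test_global_steady_state(self, steady_gene):
        p = decay_profile(steady_gene)
        assert p.kd0 == pytest.approx(0.1)
        assert [iv.t_mid for iv in p.intervals] == [2.0, 7.5, 13.5, 21.0, 33.0]
        for iv in p.intervals:
            assert iv.kd == pytest.approx(0.1, rel=1e-6)
            assert iv.kd_relative == pytest.approx(1.0, rel=1e-6)

    def test_midpoints_small_grid(self):
        g = GeneKinetics("g", TimeGrid((0, 4, 11)), np.ones(3), np.full(3, 10.0))
        p = decay_profile(g)
        assert [iv.t_mid for iv in p.intervals] == [2.0, 7.5]

    def test_kd_step_recovered(self):
        """A gene whose kd steps 0.1 -> 0.2 at the shift is inverted exactly."""
        grid = TimeGrid((0, 4, 11))
        kds = [0.2, 0.2]
        tr = np.array([1.0, 1.0, 1.0])
        ra = [10.0]  # steady state at kd0 = 0.1
        for i, kd in enumerate(kds):
            ra.append(
                rk4_forward(ra[-1], tr[i], tr[i + 1], kd, grid.times[i + 1] - grid.times[i])
            )
        g = GeneKinetics("g", grid, tr, np.array(ra, dtype=float))
        p = decay_profile(g)
        for iv in p.intervals:
            assert iv.kd == pytest.approx(0.2, rel=1e-5)
            assert iv.kd_relative == pytest.approx(2.0, rel=1e-5)


class TestTheoreticalRa:
    def test_steady_state_identity(self, steady_gene):
        assert theoretical_ra(steady_gene) == pytest.approx(steady_gene.ra, rel=1e-9)

    def test_tr_doubling_relaxes_toward_doubled_ra(self, grid):
        tr = np.array([1.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        ra = np.full(6, 10.0)
        g = GeneKinetics("g", grid, tr, ra)
        theo = theoretical_ra(g, kd0=0.1)
        assert np.all(np.diff(theo) > 0)
        assert np.all(theo <= 20.0 + 1e-9)
        assert theo[-1] > 19.0  # nearly relaxed to TR/kd0 by 40 min


class TestTemperature:
    def test_zero_activation_energy(self):
        assert temperature_factor(0, 298.15, 310.15) == 1.0

    def test_equal_temperatures(self):
        assert temperature_factor(13, 300.0, 300.0) == 1.0

    def test_closed_form_value(self):
        ea, t1, t2 = 13.0, 298.15, 310.15
        expected = math.exp((ea / 1.987e-3) * (1 / t1 - 1 / t2))
        f = temperature_factor(ea, t1, t2)
        assert f == pytest.approx(expected, rel=1e-12)
        assert 2.0 < f < 2.5

    def test_mean_factor_for_both_activation_energies_rounds_to_two(self):
        mean = np.mean(
            [temperature_factor(ea, 298.15, 310.15) for ea in (13.0, 9.7)]
        )
        assert round(mean) == 2


class TestTrCorrection:
    def test_post_shift_only(self, grid):
        g = GeneKinetics("g", grid, np.ones(6), np.full(6, 10.0))
        c = apply_tr_correction(g, 2.0)
        assert c.tr.tolist() == [1, 2, 2, 2, 2, 2]
        assert c.ra.tolist() == g.ra.tolist()

    def test_identity_factor(self, grid):
        g = GeneKinetics("g", grid, np.ones(6), np.full(6, 10.0))
        assert apply_tr_correction(g, 1.0).tr.tolist() == g.tr.tolist()

    def test_double_application_guarded(self, grid):
        g = GeneKinetics("g", grid, np.ones(6), np.full(6, 10.0))
        c = apply_tr_correction(g, 2.0)
        with pytest.raises(KineticsError):
            apply_tr_correction(c, 2.0)


class TestClassifyStability:
    def test_exact_prediction_is_unchanged(self, steady_gene):
        theo = theoretical_ra(steady_gene)
        call = classify_stability(steady_gene, theo, threshold=0.3)
        assert call.label == "unchanged"
        assert call.mean_log_ratio == pytest.approx(0.0)
        assert call.pearson_r == pytest.approx(1.0)

    def test_doubled_ra_is_stabilized(self, grid):
        theo = np.array([10.0, 9, 8, 7, 6, 5])
        g = GeneKinetics("g", grid, np.ones(6), 2 * theo)
        call = classify_stability(g, theo, threshold=0.3)
        assert call.label == "stabilized"
        assert call.mean_log_ratio == pytest.approx(1.0)

    def test_nonpositive_theoretical_is_undefined(self, grid):
        g = GeneKinetics("g", grid, np.ones(6), np.full(6, 10.0))
        theo = np.array([10.0, 5, 0.0, 5, 5, 5])
        assert classify_stability(g, theo, 0.3).label == "undefined"


class TestGlobalSummaries:
    def test_single_constant_gene(self, steady_gene):
        s = global_summaries([steady_gene])
        assert s["total_tr_relative"] == pytest.approx(np.ones(6))
        assert s["total_ra_relative"] == pytest.approx(np.ones(6))

    def test_two_genes_one_doubling(self, grid):
        a = GeneKinetics("a", grid, np.ones(6), np.full(6, 10.0))
        ra_b = np.array([10.0, 20, 20, 20, 20, 20])
        b = GeneKinetics("b", grid, np.ones(6), ra_b)
        s = global_summaries([a, b])
        assert s["total_ra_relative"].tolist() == [1.0, 1.5, 1.5, 1.5, 1.5, 1.5]
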