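import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clampmf import metad, toysystems
from clampmf.constants import KT_300
from clampmf.metad import (
    FreeEnergySurface,
    Hill,
    HillLedger,
    HillPhase,
    HillSchedule,
    basin_delta_g,
    bias_at,
    bias_on_grid,
    count_transitions,
    read_hills,
    reconstruct_fes,
    run_metadynamics,
    write_hills,
)
from clampmf.toysystems import HarmonicPotential, LangevinParams, double_well, simulate_langevin


def hill(c, h, w, t):
    return Hill(center=np.atleast_1d(c), height=h, widths=np.atleast_1d(w), deposit_time=t)


class TestBiasAt:
    def test_empty_ledger_zero(self):
        ledger = HillLedger([], ["cv1"])
        assert bias_at(ledger, 0.3, 100.0) == 0.0

    def test_single_hill_at_center(self):
        ledger = HillLedger([hill(0.5, 0.7, 0.1, 1.0)], ["cv1"])
        assert bias_at(ledger, 0.5, 2.0) == pytest.approx(0.7)

    def test_two_hills_hand_formula(self):
        ledger = HillLedger(
            [hill(0.2, 0.5, 0.1, 1.0), hill(0.6, 0.3, 0.2, 2.0)], ["cv1"]
        )
        s = 0.35
        expected = 0.5 * np.exp(-((s - 0.2) ** 2) / (2 * 0.1**2)) + 0.3 * np.exp(
            -((s - 0.6) ** 2) / (2 * 0.2**2)
        )
        assert bias_at(ledger, s, 10.0) == pytest.approx(expected, abs=1e-12)

    def test_hills_after_t_excluded(self):
        ledger = HillLedger(
            [hill(0.5, 1.0, 0.1, 1.0), hill(0.5, 1.0, 0.1, 5.0)], ["cv1"]
        )
        assert bias_at(ledger, 0.5, 2.0) == pytest.approx(1.0)
        assert bias_at(ledger, 0.5, 5.0) == pytest.approx(2.0)

    def test_truncation_beyond_5_sigma(self):
        ledger = HillLedger([hill(0.0, 1.0, 0.1, 1.0)], ["cv1"])
        assert bias_at(ledger, 0.51, 2.0) == 0.0
        assert bias_at(ledger, 0.49, 2.0) > 0.0

    def test_dimension_mismatch(self):
        ledger = HillLedger([hill(0.0, 1.0, 0.1, 1.0)], ["cv1"])
        with pytest.raises(ValueError, match="dimension"):
            bias_at(ledger, np.array([0.0, 0.0]), 1.0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_time(self, seed):
        rng = np.random.default_rng(seed)
        hills = [
            hill(rng.uniform(0, 1), rng.uniform(0.1, 1.0), rng.uniform(0.05, 0.2), t)
            for t in sorted(rng.uniform(0, 100, 8))
        ]
        ledger = HillLedger(hills, ["cv1"])
        s = rng.uniform(0, 1)
        vals = [bias_at(ledger, s, t) for t in np.linspace(0, 120, 13)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestSchedule:
    def test_phase_validation(self):
        with pytest.raises(ValueError, match="positive"):
            HillPhase(height=0.0, stride=1.0, duration=10.0)
        with pytest.raises(ValueError, match="open-ended"):
            HillSchedule([HillPhase(0.5, 1.0, None), HillPhase(0.2, 1.0, 10.0)])

    def test_expected_hill_count(self):
        sched = HillSchedule(
            [HillPhase(0.5, 1.0, 10.0), HillPhase(0.2, 2.0, 20.0), HillPhase(0.05, 0.5, None)]
        )
        assert sched.expected_hill_count(30.0) == 10 + 10
        assert sched.expected_hill_count(40.0) == 10 + 10 + 20


class TestRunMetadynamics:
    def test_zero_schedule_identical_to_unbiased(self):
        pot = double_well(0.4, 1.0, 3.0, 0.5)
        params = LangevinParams(timestep=0.001, n_steps=5000, seed=3, save_stride=5)
        plain = simulate_langevin(pot, params, x0=0.4)
        res = run_metadynamics(pot, HillSchedule([]), 0.05, params, x0=0.4)
        assert len(res.ledger) == 0
        np.testing.assert_array_equal(res.trajectory.positions, plain.positions)

    def test_deposition_count_matches_schedule(self):
        pot = HarmonicPotential(k=10.0)
        sched = HillSchedule([HillPhase(0.3, 1.0, 10.0), HillPhase(0.1, 2.0, None)])
        params = LangevinParams(timestep=0.01, n_steps=3000, seed=4)  # 30 ps
        res = run_metadynamics(pot, sched, 0.05, params)
        assert len(res.ledger) == sched.expected_hill_count(30.0)

    def test_ledger_times_non_decreasing(self):
        pot = HarmonicPotential(k=10.0)
        sched = HillSchedule([HillPhase(0.3, 0.5, None)])
        params = LangevinParams(timestep=0.01, n_steps=500, seed=5)
        res = run_metadynamics(pot, sched, 0.05, params)
        times = [h.deposit_time for h in res.ledger.hills]
        assert all(b >= a for a, b in zip(times, times[1:]))

    def test_2d_smoke(self):
        pot = HarmonicPotential(k=10.0, dimension=2)
        sched = HillSchedule([HillPhase(0.2, 1.0, None)])
        params = LangevinParams(timestep=0.005, n_steps=2000, seed=6)
        res = run_metadynamics(pot, sched, [0.05, 0.08], params)
        assert res.ledger.dimension == 2
        assert len(res.ledger) == 10
        assert res.trajectory.positions.shape[1] == 2


class TestReconstructFes:
    def test_flat_potential_filled_flat(self):
        class FlatBox(toysystems.AnalyticPotential):
            """U = 0 on [0, 1], quadratic walls outside."""

            dimension = 1
            k = 500.0

            def value(self, x):
                x = float(np.atleast_1d(x)[0])
                if x < 0:
                    return 0.5 * self.k * x * x
                if x > 1:
                    return 0.5 * self.k * (x - 1) ** 2
                return 0.0

            def gradient(self, x):
                x = float(np.atleast_1d(x)[0])
                if x < 0:
                    return self.k * x
                if x > 1:
                    return self.k * (x - 1)
                return 0.0

        sched = HillSchedule([HillPhase(0.2, 0.5, 100.0), HillPhase(0.05, 0.5, None)])
        params = LangevinParams(timestep=0.001, n_steps=400000, seed=7, save_stride=20)
        res = run_metadynamics(FlatBox(), sched, 0.1, params, x0=0.5)
        grid = np.linspace(-1.0, 2.0, 601)
        fes = reconstruct_fes(res.ledger, grid, average_window=100.0)
        inner = (grid > 0.1) & (grid < 0.9)
        # the filled box interior is flat within ~(twice) the coarse hill height
        assert np.ptp(fes.values[inner]) < 2 * 0.2

    def test_grid_must_cover_hills(self):
        ledger = HillLedger([hill(0.5, 0.2, 0.1, 1.0)], ["cv1"])
        with pytest.raises(ValueError, match="cover"):
            reconstruct_fes(ledger, np.linspace(0.4, 0.6, 10))

    def test_fes_from_ledger_is_minus_bias(self):
        ledger = HillLedger(
            [hill(0.3, 0.5, 0.1, 1.0), hill(0.7, 0.2, 0.1, 2.0)], ["cv1"]
        )
        grid = np.linspace(-0.3, 1.3, 161)
        fes = reconstruct_fes(ledger, grid)
        direct = -np.array([bias_at(ledger, x, 2.0) for x in grid])
        direct -= direct.min()
        np.testing.assert_allclose(fes.values, direct, atol=1e-12)

    def test_row_permutation_invariant_at_equal_times(self):
        h1 = hill(0.3, 0.5, 0.1, 1.0)
        h2 = hill(0.7, 0.2, 0.1, 1.0)
        grid = np.linspace(-0.3, 1.3, 81)
        f_a = reconstruct_fes(HillLedger([h1, h2], ["cv1"]), grid)
        f_b = reconstruct_fes(HillLedger([h2, h1], ["cv1"]), grid)
        np.testing.assert_allclose(f_a.values, f_b.values, atol=1e-12)

    def test_planted_asymmetry_recovered(self, staged_double_well_run):
        pot, _, _, res = staged_double_well_run
        grid = np.linspace(-0.4, 1.9, 1151)
        fes = reconstruct_fes(res.ledger, grid, average_window=700.0)
        dg = basin_delta_g(fes, [(0.8, 1.2)], [(0.2, 0.6)], KT_300)
        assert dg.min_to_min == pytest.approx(1.0, abs=0.3)

    def test_staged_schedule_beats_constant_coarse(self, staged_double_well_run):
        pot, _, params, staged = staged_double_well_run
        coarse_params = LangevinParams(
            timestep=params.timestep,
            n_steps=1100000,  # the pile-up of 0.5 hills destabilizes longer runs
            seed=params.seed,
            save_stride=params.save_stride,
        )
        coarse = run_metadynamics(
            pot,
            HillSchedule([HillPhase(0.5, 1.0, None)]),
            widths=0.05,
            params=coarse_params,
            x0=0.4,
        )
        grid = np.linspace(-0.6, 2.1, 1351)

        def dg_ripple(result, t_lo, t_hi, n=25):
            vals = []
            for t in np.linspace(t_lo, t_hi, n):
                fes = reconstruct_fes(result.ledger, grid, t_final=t)
                dg = basin_delta_g(fes, [(0.8, 1.2)], [(0.2, 0.6)], KT_300)
                vals.append(dg.min_to_min)
            return np.std(vals)

        # compare bias histories over the same epoch window
        assert dg_ripple(staged, 800.0, 1100.0) < dg_ripple(coarse, 800.0, 1100.0)


class TestBasinDeltaG:
    def test_symmetric_double_well_zero(self):
        grid = np.linspace(-1.0, 1.0, 201)
        values = (grid**2 - 0.25) ** 2 * 10
        values -= values.min()
        fes = FreeEnergySurface([grid], values)
        dg = basin_delta_g(fes, [(-1.0, 0.0)], [(0.0, 1.0)], KT_300)
        assert dg.integrated == pytest.approx(0.0, abs=1e-9)
        assert dg.min_to_min == pytest.approx(0.0, abs=1e-12)

    def test_same_region_zero(self):
        grid = np.linspace(0.0, 1.0, 101)
        fes = FreeEnergySurface([grid], np.sin(grid * 3) - np.sin(grid * 3).min())
        dg = basin_delta_g(fes, [(0.2, 0.4)], [(0.2, 0.4)], KT_300)
        assert dg.integrated == 0.0

    def test_narrow_deep_wells_agree_with_min_to_min(self):
        grid = np.linspace(-1.0, 1.0, 2001)
        delta = 2.0
        values = np.minimum(
            200 * (grid + 0.5) ** 2, 200 * (grid - 0.5) ** 2 + delta
        )
        values -= values.min()
        fes = FreeEnergySurface([grid], values)
        dg = basin_delta_g(fes, [(0.0, 1.0)], [(-1.0, 0.0)], KT_300)
        assert dg.min_to_min == pytest.approx(delta, abs=1e-9)
        assert dg.integrated == pytest.approx(dg.min_to_min, abs=0.1)

    def test_empty_basin_raises(self):
        grid = np.linspace(0.0, 1.0, 11)
        fes = FreeEnergySurface([grid], np.zeros(11))
        with pytest.raises(ValueError, match="no grid points"):
            basin_delta_g(fes, [(2.0, 3.0)], [(0.0, 1.0)], KT_300)


class TestTransitions:
    def test_metadynamics_crosses_where_unbiased_does_not(self, staged_double_well_run):
        pot, _, params, res = staged_double_well_run
        barrier = pot.maxima[0]
        biased = count_transitions(res.trajectory.positions[:, 0], barrier, margin=0.1)
        unbiased = simulate_langevin(pot, params, x0=0.4)
        free = count_transitions(unbiased.positions[:, 0], barrier, margin=0.1)
        assert biased > 10
        assert free == 0

    def test_counting_with_hysteresis(self):
        series = np.array([0.0, 1.0, 0.45, 0.55, 0.0, 1.0])
        # margin suppresses the barrier-top jitter at 0.45/0.55
        assert count_transitions(series, 0.5, margin=0.1) == 3


class TestHillsIO:
    def test_roundtrip(self):
        ledger = HillLedger(
            [hill(0.2, 0.5, 0.1, 1.0), hill([0.6], 0.3, [0.2], 2.0)], ["dist"]
        )
        again = read_hills(write_hills(ledger))
        assert len(again) == 2
        assert again.cv_names == ["dist"]
        for a, b in zip(again.hills, ledger.hills):
            np.testing.assert_allclose(a.center, b.center)
            np.testing.assert_allclose(a.widths, b.widths)
            assert a.height == pytest.approx(b.height)
            assert a.deposit_time == pytest.approx(b.deposit_time)

    def test_hand_written_file(self):
        text = (
            "#! FIELDS time cv1 sigma_cv1 height\n"
            "1.0 0.25 0.05 0.5\n"
            "2.0 0.35 0.05 0.2\n"
        )
        ledger = read_hills(text)
        assert len(ledger) == 2
        assert ledger.hills[0].center[0] == 0.25
        assert ledger.hills[1].height == 0.2

    def test_plumed_style_2d_fixture(self):
        # PLUMED-1.x style: time, two CVs, two sigmas, height
        text = (
            "#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height\n"
            "10.0 0.1 -0.2 0.05 0.07 0.35\n"
            "20.0 0.15 -0.1 0.05 0.07 0.35\n"
        )
        ledger = read_hills(text)
        assert ledger.dimension == 2
        np.testing.assert_allclose(ledger.hills[0].center, [0.1, -0.2])
        np.testing.assert_allclose(ledger.hills[0].widths, [0.05, 0.07])
        assert ledger.hills[0].height == 0.35
        assert ledger.hills[0].deposit_time == 10.0

    def test_ragged_row_names_line(self):
        text = "#! FIELDS time cv1 sigma_cv1 height\n1.0 0.25 0.05 0.5\n2.0 0.35\n"
        with pytest.raises(ValueError, match="line 3"):
            read_hills(text)


class TestGridBias:
    def test_bias_on_grid_matches_pointwise(self):
        ledger = HillLedger(
            [hill(0.3, 0.5, 0.1, 1.0), hill(0.7, 0.2, 0.15, 2.0)], ["cv1"]
        )
        grid = [np.linspace(0.0, 1.0, 51)]
        v = bias_on_grid(ledger, grid, 5.0)
        pointwise = np.array([bias_at(ledger, x, 5.0) for x in grid[0]])
        np.testing.assert_allclose(v, pointwise, atol=1e-12)

    def test_2d_grid(self):
        ledger = HillLedger(
            [Hill(np.array([0.2, 0.5]), 0.4, np.array([0.1, 0.1]), 1.0)],
            ["cv1", "cv2"],
        )
        axes = [np.linspace(0, 1, 21), np.linspace(0, 1, 31)]
        v = bias_on_grid(ledger, axes, 2.0)
        assert v.shape == (21, 31)
        i = np.argmin(np.abs(axes[0] - 0.2))
        j = np.argmin(np.abs(axes[1] - 0.5))
        assert v[i, j] == pytest.approx(0.4, abs=1e-6)
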