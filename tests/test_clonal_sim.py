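"""Unit and property tests for the two-state clonal simulator."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonfate import (ChemoSchedule, CloneTable, ExperimentDesign, MechanismSpec,
                      RateSet, make_mechanism_rates, nutrient_level, run_experiment,
                      seed_library, sort_sample, step, step_gillespie)
from clonfate.clonal_sim import StepSizeError
from clonfate.config import DEFAULT_RATES


def _ztp_multi_fraction(infection_prob: float) -> float:
    """Oracle: P(k >= 2 | k >= 1) for k ~ Poisson(-ln(1-p)), by direct summation."""
    lam = -math.log(1.0 - infection_prob)
    p0 = math.exp(-lam)
    p1 = lam * p0
    return (1.0 - p0 - p1) / (1.0 - p0)


class TestSeedLibrary:
    def test_founder_count_matches_infection_probability(self):
        t = seed_library(2_000_000, 0.1, 10_000_000, seed=42)
        expected = 2_000_000 * 0.1
        sd = math.sqrt(2_000_000 * 0.1 * 0.9)
        assert abs(t.meta["n_founders"] - expected) <= 3 * sd
        # distinct-barcode assignment keeps clone counts equal to founders
        assert t.n_clones == t.meta["n_founders"]
        assert t.total_burden == t.meta["n_founders"]

    def test_zero_infection_gives_empty_table(self):
        t = seed_library(10_000, 0.0, 1000, seed=0)
        assert t.n_clones == 0
        assert t.total_burden == 0

    def test_multi_integration_fraction_matches_truncated_poisson(self):
        t = seed_library(1_000_000, 0.1, 10_000_000, seed=7)
        frac = t.meta["n_multi_integration"] / t.meta["n_founders"]
        oracle = _ztp_multi_fraction(0.1)
        sd = math.sqrt(oracle * (1 - oracle) / t.meta["n_founders"])
        assert abs(frac - oracle) <= 4 * sd

    def test_initial_state_assignment(self):
        t = seed_library(200_000, 0.1, 10_000_000, initial_high_fraction=1.0, seed=1)
        assert t.total_L == 0
        t2 = seed_library(200_000, 0.1, 10_000_000, initial_high_fraction=0.0, seed=1)
        assert t2.total_H == 0

    @pytest.mark.parametrize("kwargs", [
        dict(n_exposed_cells=-1, infection_prob=0.1, library_size=10),
        dict(n_exposed_cells=10, infection_prob=1.5, library_size=10),
        dict(n_exposed_cells=10, infection_prob=0.1, library_size=0),
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            seed_library(**kwargs, seed=0)

    def test_small_library_warns_on_collisions(self):
        with pytest.warns(UserWarning, match="collision"):
            seed_library(10_000, 0.5, 100, seed=0)


class TestMechanismRates:
    def test_selection_template_has_exactly_zero_transitions(self):
        r = make_mechanism_rates(MechanismSpec("selection"), DEFAULT_RATES)
        assert r.trans_HL == 0.0 and r.trans_LH == 0.0
        assert r.nutrient_coupling == 0.0
        assert r.kill_L > r.kill_H

    def test_induction_template_symmetrises_transitions(self):
        base = RateSet(0.5, 0.3, 0.05, 0.05, 0.1, 0.3, 0.8, 1.1,
                       nutrient_coupling=1.0)
        r = make_mechanism_rates(MechanismSpec("induction"), base)
        assert r.trans_HL == r.trans_LH == pytest.approx(0.2)
        assert r.nutrient_coupling > 0

    def test_mixed_is_arithmetic_mean_of_templates(self):
        sel = make_mechanism_rates(MechanismSpec("selection"), DEFAULT_RATES)
        ind = make_mechanism_rates(MechanismSpec("induction"), DEFAULT_RATES)
        mix = make_mechanism_rates(MechanismSpec("mixed", 0.5), DEFAULT_RATES)
        for f in ("birth_H", "death_L", "trans_HL", "trans_LH", "kill_H",
                  "kill_L", "nutrient_coupling"):
            assert getattr(mix, f) == pytest.approx(
                0.5 * (getattr(sel, f) + getattr(ind, f)))

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError):
            MechanismSpec("drift")

    def test_induction_requires_transitions_and_coupling(self):
        flat = RateSet(0.5, 0.3, 0.05, 0.05, 0.0, 0.0, 0.8, 1.1)
        with pytest.raises(ValueError):
            make_mechanism_rates(MechanismSpec("induction"), flat)


class TestNutrient:
    def test_boundary_values(self):
        assert nutrient_level(0, 1e8) == 1.0
        assert nutrient_level(1e8, 1e8) == 0.5

    def test_strictly_decreasing_in_burden(self):
        k = 2e8
        grid = np.linspace(0, 10 * k, 101)
        vals = [nutrient_level(b, k) for b in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_capacity(self):
        with pytest.raises(ValueError):
            nutrient_level(10, 0.0)


class TestStep:
    def test_null_dynamics_identity(self, small_clone_table):
        zero = RateSet(0, 0, 0, 0, 0, 0, 0, 0)
        out = step(small_clone_table, zero, False, 0.5, 0.7, seed=3)
        np.testing.assert_array_equal(out.n_H, small_clone_table.n_H)
        np.testing.assert_array_equal(out.n_L, small_clone_table.n_L)

    @pytest.mark.parametrize("birth,death", [(0.5, 0.0), (0.5, 0.2)])
    def test_birth_death_mean_matches_analytic(self, birth, death):
        """Mean of the leap process matches N0*exp((b-d)t) within 3 SE."""
        rates = RateSet(birth, 0.0, death, 0.0, 0, 0, 0, 0)
        rng = np.random.default_rng(99)
        finals = []
        for _ in range(200):
            t = CloneTable(np.array([0]), np.array([1000]), np.array([0]))
            for _ in range(40):
                t = step(t, rates, False, 1.0, 0.1, rng)
            finals.append(t.total_burden)
        finals = np.asarray(finals, dtype=float)
        target = 1000 * math.exp((birth - death) * 4.0)
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - target) <= 3 * se

    def test_state_restricted_kill(self):
        rates = RateSet(0, 0, 0, 0, 0, 0, kill_H=0.0, kill_L=5.0)
        t = CloneTable(np.array([0]), np.array([500]), np.array([500]))
        rng = np.random.default_rng(4)
        for _ in range(200):
            t = step(t, rates, True, 1.0, 0.1, rng)
        assert int(t.n_H[0]) == 500       # no hazards act on H
        assert int(t.n_L[0]) == 0

    def test_kill_inactive_outside_chemo_window(self, small_clone_table):
        rates = RateSet(0, 0, 0, 0, 0, 0, kill_H=5.0, kill_L=5.0)
        out = step(small_clone_table, rates, False, 1.0, 0.1, seed=0)
        assert out.total_burden == small_clone_table.total_burden

    def test_step_size_error(self, small_clone_table):
        rates = RateSet(0, 0, 6.0, 0, 0, 0, 0, 0)
        with pytest.raises(StepSizeError, match="reduce dt"):
            step(small_clone_table, rates, False, 1.0, 0.5, seed=0)

    @given(st.integers(1, 6), st.floats(0.05, 0.9), st.floats(0.05, 0.9),
           st.integers(0, 2 ** 20))
    def test_transitions_conserve_per_clone_totals(self, n_clones, t_hl, t_lh, seed):
        """With transitions only, n_H + n_L per clone is invariant."""
        r = np.random.default_rng(seed)
        n_H = r.integers(0, 50, n_clones)
        n_L = r.integers(0, 50, n_clones)
        t = CloneTable(np.arange(n_clones), n_H, n_L)
        rates = RateSet(0, 0, 0, 0, t_hl, t_lh, 0, 0, nutrient_coupling=0.3)
        out = t
        for _ in range(5):
            out = step(out, rates, False, 0.6, 0.1, r)
        np.testing.assert_array_equal(out.n_H + out.n_L, n_H + n_L)

    def test_stationarity_under_symmetric_transitions(self):
        """Symmetric transitions, no birth/death: H occupancy converges to 1/2."""
        rates = RateSet(0, 0, 0, 0, 1.0, 1.0, 0, 0)
        t = CloneTable(np.array([0]), np.array([20_000]), np.array([0]))
        rng = np.random.default_rng(11)
        for _ in range(100):
            t = step(t, rates, False, 0.0, 0.1, rng)
        frac = t.total_H / t.total_burden
        assert abs(frac - 0.5) < 0.02

    def test_gillespie_cross_validation(self):
        """Tau-leap and exact SSA agree on the mean of a small mixed process."""
        rates = RateSet(0.3, 0.2, 0.1, 0.1, 0.2, 0.2, 0, 0)
        rng = np.random.default_rng(5)
        leap, exact = [], []
        for _ in range(60):
            t0 = CloneTable(np.array([0, 1]), np.array([200, 100]),
                            np.array([100, 200]))
            t = t0
            for _ in range(20):
                t = step(t, rates, False, 0.5, 0.1, rng)
            leap.append(t.total_burden)
            g = step_gillespie(t0, rates, False, 0.5, 2.0, rng)
            exact.append(g.total_burden)
        leap, exact = np.asarray(leap, float), np.asarray(exact, float)
        se = math.hypot(leap.std(ddof=1) / math.sqrt(len(leap)),
                        exact.std(ddof=1) / math.sqrt(len(exact)))
        assert abs(leap.mean() - exact.mean()) <= 3 * se


class TestSortSample:
    def test_exhaustive_sampling_returns_exact_counts(self, small_clone_table):
        counts, trunc = sort_sample(small_clone_table, "H",
                                    small_clone_table.total_H, seed=0)
        np.testing.assert_array_equal(counts.to_numpy(), small_clone_table.n_H)
        assert not trunc

    def test_zero_draw(self, small_clone_table):
        counts, trunc = sort_sample(small_clone_table, "L", 0, seed=0)
        assert counts.sum() == 0 and not trunc

    def test_truncation_flag(self, small_clone_table):
        counts, trunc = sort_sample(small_clone_table, "H", 10 ** 6, seed=0)
        assert trunc
        assert counts.sum() == small_clone_table.total_H

    def test_degenerate_single_clone_support(self):
        t = CloneTable(np.array([7, 8]), np.array([1000, 0]), np.array([0, 50]))
        counts, _ = sort_sample(t, "H", 400, seed=1)
        assert counts[7] == 400 and counts[8] == 0

    def test_counts_sum_and_bounds(self, small_clone_table, rng):
        counts, _ = sort_sample(small_clone_table, "L", 60, rng)
        assert counts.sum() == 60
        assert (counts.to_numpy() <= small_clone_table.n_L).all()


class TestChemoSchedule:
    def test_window(self):
        s = ChemoSchedule(start_day=0.0, arac_days=5, dox_days=3)
        assert s.active(0.0) and s.active(4.9) and not s.active(5.0)
        assert not s.active(-0.1)

    def test_invalid_durations(self):
        with pytest.raises(ValueError):
            ChemoSchedule(arac_days=2, dox_days=3)


class TestRunExperiment:
    DESIGN = ExperimentDesign(
        n_exposed_cells=30_000, infection_prob=0.1, library_size=10 ** 7,
        n_transplanted=3000, sampling_days=(0.0, 3.0), n_sorted_per_gate=500,
        growth_days=5.0, seed=5,
    )

    def test_determinism_same_seed(self):
        a = run_experiment(self.DESIGN, MechanismSpec("induction"), DEFAULT_RATES)
        b = run_experiment(self.DESIGN, MechanismSpec("induction"), DEFAULT_RATES)
        np.testing.assert_array_equal(a.burden, b.burden)
        for key in a.sorted_counts:
            assert a.sorted_counts[key].equals(b.sorted_counts[key])

    def test_zero_kill_burden_nondecreasing(self):
        rates = RateSet(0.5, 0.3, 0.0, 0.0, 0.2, 0.2, 0.0, 0.0,
                        nutrient_coupling=1.0)
        traj = run_experiment(self.DESIGN, MechanismSpec("induction"), rates)
        assert traj.burden_at(3.0) >= traj.burden_at(0.0)

    def test_extinction_flagged_not_raised(self):
        rates = RateSet(0.0, 0.0, 8.0, 8.0, 0, 0, 0, 0)
        design = ExperimentDesign(
            n_exposed_cells=2000, infection_prob=0.1, library_size=10 ** 6,
            n_transplanted=150, sampling_days=(0.0, 3.0), n_sorted_per_gate=100,
            growth_days=5.0, dt=0.1, dt_growth=0.1, seed=2,
        )
        traj = run_experiment(design, None, rates)
        assert traj.extinct

    def test_sampling_days_on_grid(self):
        traj = run_experiment(self.DESIGN, MechanismSpec("induction"), DEFAULT_RATES)
        assert set(traj.snapshots) == {0.0, 3.0}
        for day, snap in traj.snapshots.items():
            assert snap.total_burden == traj.burden_at(day)

    def test_selection_clones_stay_mono_state(self):
        traj = run_experiment(self.DESIGN, MechanismSpec("selection"), DEFAULT_RATES)
        for snap in traj.snapshots.values():
            both = (snap.n_H > 0) & (snap.n_L > 0)
            assert int(both.sum()) == 0
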