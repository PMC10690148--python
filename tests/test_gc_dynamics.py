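"""Stochastic GC dynamics: single-step law, whole-node simulation properties."""

import numpy as np
import pytest

from edisim.gc import (
    NATIVE,
    NONNATIVE,
    AntigenState,
    ConfigurationError,
    GCParams,
    GCPopulation,
    UndefinedFractionError,
    gc_step,
    native_gc_fraction,
    native_ic_fraction,
    simulate_gc,
)
from edisim.regimens import Regimen, parse_regimen
from helpers import make_population


class TestGcStepLaw:
    def test_no_fdc_antigen_no_births_decay_at_death_plus_exit(self):
        # with empty IC pools capture is zero for every cell, so no births;
        # the population declines at mu_death + p_exit per day
        p = GCParams(gc_capacity=10 ** 9)
        rng = np.random.default_rng(0)
        n0 = 40000
        pop = make_population(np.full(n0, 6.0), np.zeros(n0), np.zeros(n0), 1)
        antigen = AntigenState()  # all pools zero
        for _ in range(10):
            pop, _ = gc_step(pop, antigen, p, rng)
        expected = n0 * (1 - (p.mu_death + p.p_exit) * p.dt) ** 10
        assert pop.size == pytest.approx(expected, rel=0.02)

    def test_identical_cells_get_identical_event_probabilities(self):
        # exchangeability: per-cell birth counts agree across positions
        p = GCParams(gc_capacity=10 ** 9)
        antigen = AntigenState(ic_native=0.2)
        rng = np.random.default_rng(1)
        counts = np.zeros(3)
        for _ in range(3000):
            pop = make_population([6.0] * 3, [NATIVE] * 3, [0] * 3, 1)
            new, _ = gc_step(pop, antigen, p, rng)
            for lineage in range(3):
                counts[lineage] += (new.lineage == lineage).sum()
        assert counts.std() / counts.mean() < 0.05

    def test_three_cell_step_statistics_match_enumeration(self):
        # independent oracle: per-cell event probabilities computed from the
        # step's law, expectations by enumerating outcomes; compared against
        # 1e5 replicated GCs run in a single vectorized call
        p = GCParams(gc_capacity=10 ** 9)
        antigen = AntigenState(ic_native=0.11, ic_nonnative=0.23)
        affs = np.array([5.6, 6.2, 5.9])
        epis = np.array([NATIVE, NONNATIVE, NONNATIVE])
        m = 100_000
        pop = make_population(
            np.tile(affs, m), np.tile(epis, m), np.repeat(np.arange(m), 3), m)
        rng = np.random.default_rng(7)
        new, (exit_epi, _) = gc_step(pop, antigen, p, rng)

        # oracle: recompute the law directly
        ic = np.where(epis == NATIVE, antigen.ic_native, antigen.ic_nonnative)
        s = 10.0 ** (affs - p.aff_capture_ref) * ic / p.K_ic
        c = s / (1 + s)
        help_ = np.minimum(1.0, c / (c.mean() + p.help_threshold))
        p_death = p.mu_death * p.dt
        p_exit = p.p_exit * p.dt
        p_div = p.beta_max * c * help_ * p.dt
        # each of the 3 positions: survives unless death/exit; daughter added
        # with prob p_div * (1 - p_lethal)
        expected_size = 3 - 3 * (p_death + p_exit) + (
            p_div.sum() * (1 - p.p_lethal))
        expected_exits = 3 * p_exit
        got_size = new.size / m
        got_exits = len(exit_epi) / m
        # binomial standard errors at m trials
        assert got_size == pytest.approx(expected_size, abs=0.01)
        assert got_exits == pytest.approx(expected_exits, abs=0.001)
        # position-resolved: daughters inherit the parent's lineage id, so
        # the count per position is survivors plus viable daughters
        for lineage in range(3):
            count = (new.lineage % 3 == lineage).sum()
            expect = m * (1 - p_death - p_exit + p_div[lineage] * (1 - p.p_lethal))
            assert count == pytest.approx(expect, abs=4 * np.sqrt(m))

    def test_higher_affinity_cells_divide_more(self):
        # monotone selection: in a mixed GC the high-affinity subset must
        # produce more daughters per capita
        p = GCParams(gc_capacity=10 ** 9)
        antigen = AntigenState(ic_native=0.15)
        m = 30_000
        affs = np.tile([5.4, 6.4], m)
        pop = make_population(affs, np.zeros(2 * m), np.repeat(np.arange(m), 2), m)
        rng = np.random.default_rng(3)
        new, _ = gc_step(pop, antigen, p, rng)
        low = (new.affinity < 5.9).sum()
        high = (new.affinity >= 5.9).sum()
        assert high > low

    def test_capacity_never_exceeded(self):
        p = GCParams(n_gc=3, gc_capacity=50)
        antigen = AntigenState(ic_native=1.0, ic_nonnative=1.0)
        n0 = 45
        pop = make_population(
            np.full(3 * n0, 6.5), np.zeros(3 * n0),
            np.repeat(np.arange(3), n0), 3)
        rng = np.random.default_rng(5)
        for _ in range(400):
            pop, _ = gc_step(pop, antigen, p, rng)
            assert pop.counts().max() <= 50

    def test_overlarge_dt_raises_configuration_error(self):
        with pytest.raises(ConfigurationError):
            GCParams(dt=0.5)

    def test_mutation_effects_mostly_deleterious_small_beneficial_tail(self):
        # the affinity-change distribution has ~5% beneficial draws
        p = GCParams()
        rng = np.random.default_rng(0)
        delta = p.mut_shift - np.exp(rng.normal(p.mut_mu, p.mut_sigma, 200_000))
        beneficial = (delta > 0).mean()
        assert 0.02 < beneficial < 0.10
        assert np.median(delta) < 0


class TestSimulateGc:
    def test_zero_antigen_regimen_all_outputs_zero(self, small_gc_params):
        out = simulate_gc(small_gc_params, Regimen((), label="none"),
                          t_end=5.0, n_replicates=2, seed=0)
        assert out.mean["gc_b"].max() == 0
        assert out.mean["titer_native"].max() == 0
        assert out.mean[["sol_native", "ic_native", "ic_nonnative"]].to_numpy().max() == 0

    def test_same_seed_reproduces_output_exactly(self, small_gc_params):
        reg = parse_regimen("2ed")
        a = simulate_gc(small_gc_params, reg, t_end=6.0, n_replicates=2, seed=42)
        b = simulate_gc(small_gc_params, reg, t_end=6.0, n_replicates=2, seed=42)
        assert a.mean.equals(b.mean)
        assert a.seeds == b.seeds

    def test_different_seeds_differ(self, small_gc_params):
        reg = parse_regimen("2ed")
        a = simulate_gc(small_gc_params, reg, t_end=6.0, n_replicates=1, seed=1)
        b = simulate_gc(small_gc_params, reg, t_end=6.0, n_replicates=1, seed=2)
        assert not a.mean["gc_b"].equals(b.mean["gc_b"])

    def test_all_native_gc_without_degradation(self):
        # with conversion off only native antigen ever exists, so every
        # recruited B cell is native-specific
        p = GCParams(k_deg=0.0, n_gc=6, gc_capacity=300)
        out = simulate_gc(p, parse_regimen("bolus"), t_end=4.0,
                          n_replicates=2, seed=9)
        assert native_gc_fraction(out, 4.0) == pytest.approx(1.0, abs=1e-12)

    def test_native_fraction_half_when_both_pools_equal(self):
        # direct symmetry check at the step level via equal IC pools
        p = GCParams(precursor_freq_native=0.5, precursor_freq_nonnative=0.5,
                     germline_aff_native=5.8, germline_aff_nonnative=5.8,
                     gc_capacity=10 ** 9)
        antigen = AntigenState(ic_native=0.2, ic_nonnative=0.2)
        rng = np.random.default_rng(11)
        n0 = 20000
        epis = rng.random(n0) < 0.5
        pop = make_population(np.full(n0, 5.8), np.where(epis, 0, 1),
                              np.zeros(n0), 1)
        for _ in range(200):
            pop, _ = gc_step(pop, antigen, p, rng)
        frac = (pop.epitope == NATIVE).mean()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_replicate_seeds_recorded_and_derived_from_seed(self, small_gc_params):
        out = simulate_gc(small_gc_params, parse_regimen("bolus"), t_end=2.0,
                          n_replicates=3, seed=17)
        assert out.seeds == [[17, 0], [17, 1], [17, 2]]
        assert out.n_replicates == 3

    def test_fraction_accessors_and_errors(self, small_gc_params):
        out = simulate_gc(small_gc_params, Regimen((), label="none"),
                          t_end=2.0, n_replicates=1, seed=0)
        with pytest.raises(UndefinedFractionError):
            native_ic_fraction(out, 1.0)
        with pytest.raises(UndefinedFractionError):
            native_gc_fraction(out, 1.0)
        with pytest.raises(ValueError):
            out.at("gc_b", 10.0)  # beyond simulated range

    def test_native_ic_fraction_is_one_without_degradation(self):
        p = GCParams(k_deg=0.0, n_gc=6, gc_capacity=300)
        out = simulate_gc(p, parse_regimen("2ed"), t_end=10.0,
                          n_replicates=2, seed=3)
        assert native_ic_fraction(out, 10.0) == pytest.approx(1.0, abs=1e-12)


class TestDefaultParameterBehaviour:
    """Properties of the shipped calibration, on the shared session runs."""

    def test_day21_fdc_antigen_ordering(self, gc_runs):
        ic = {
            name: gc_runs[name].at("ic_native", 21.0)
            + gc_runs[name].at("ic_nonnative", 21.0)
            for name in ("bolus", "2ed", "7ed")
        }
        assert ic["bolus"] < ic["2ed"] < ic["7ed"]

    def test_day21_native_gc_fraction_ordering(self, gc_runs):
        frac = {name: native_gc_fraction(gc_runs[name], 21.0)
                for name in ("bolus", "2ed", "7ed")}
        assert frac["bolus"] < frac["2ed"] < frac["7ed"]

    def test_gc_sizes_similar_at_day7_diverged_at_day14(self, gc_runs):
        b7 = gc_runs["bolus"].at("gc_b", 7.0)
        t7 = gc_runs["2ed"].at("gc_b", 7.0)
        assert 0.5 < t7 / b7 < 2.0
        assert gc_runs["2ed"].at("gc_b", 14.0) > gc_runs["bolus"].at("gc_b", 14.0)

    def test_antigen_mass_balance_all_regimens(self, gc_runs):
        for name, out in gc_runs.items():
            for audit, rep in zip(out.audits, out.replicates):
                last = rep.iloc[-1]
                total = (last.sol_native + last.sol_nonnative
                         + last.ic_native + last.ic_nonnative)
                residual = audit.input - (
                    total + audit.cleared_soluble + audit.decayed_ic)
                assert abs(residual) < 1e-8, name

    def test_gc_population_never_exceeds_total_capacity(self, gc_runs, gc_params):
        cap = gc_params.n_gc * gc_params.gc_capacity
        for out in gc_runs.values():
            for rep in out.replicates:
                assert rep["gc_b"].max() <= cap

    def test_affinity_maturation_of_dominant_lineages(self, gc_runs):
        # replicate-mean non-native GC affinity rises once the response is
        # established (day 11 onward) in the 2-ED node
        m = gc_runs["2ed"].mean
        days = [11.0, 14.0, 17.0, 21.0]
        vals = [float(np.interp(d, m["time_day"], m["aff_nonnative_mean"]))
                for d in days]
        assert all(b >= a - 0.02 for a, b in zip(vals, vals[1:]))
        assert vals[-1] > vals[0]

    def test_replicate_means_stable_under_doubling(self, gc_runs):
        # day-21 native IC fraction from 5 vs 10 replicates within 10%
        out = gc_runs["2ed"]
        def frac_from(reps):
            icn = np.mean([r.iloc[-1].ic_native for r in reps])
            icnn = np.mean([r.iloc[-1].ic_nonnative for r in reps])
            return icn / (icn + icnn)
        half = frac_from(out.replicates[:5])
        full = frac_from(out.replicates)
        assert abs(full - half) / full < 0.10
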