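import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prosofix import (
    EvolutionModel,
    FecundityMap,
    GoodsScheme,
    closed_form_star_ff,
    death_rates,
    initialization,
    kernel_cycle_db,
    kernel_star_bd,
    make_cycle,
    make_star,
    mean_fixation,
    mean_rho,
    solve_fixation,
    star_ff_profile,
)

SCHEME = GoodsScheme("ff", 5, 1)


class TestSolver:
    @pytest.mark.parametrize("kind", ["pp", "ff", "cf"])
    def test_neutral_cycle_is_gamblers_ruin(self, kind):
        N = 11
        fr = solve_fixation(kernel_cycle_db(N, GoodsScheme(kind, 4, 1), FecundityMap(0.0)))
        assert np.abs(fr.rho_C - np.arange(N + 1) / N).max() < 1e-10

    def test_boundary_conditions_and_complement(self):
        k = kernel_star_bd(8, GoodsScheme("cf", 5, 1), FecundityMap(1.2))
        fr = solve_fixation(k)
        assert fr.rho_C[k.space.i_all_C] == 1.0
        assert fr.rho_C[k.space.i_all_D] == 0.0
        assert np.allclose(fr.rho_D, 1.0 - fr.rho_C)
        assert np.all((fr.rho_C >= 0) & (fr.rho_C <= 1))


class TestDeathRates:
    def test_db_replacement_is_uniform_on_any_graph(self):
        g = make_star(9)
        d = death_rates(g, "dB", "C", SCHEME, FecundityMap(2.0))
        assert np.allclose(d, 1 / 9)

    def test_star_bd_all_nonproducers_hub_replaced_most(self):
        N = 10
        d = death_rates(make_star(N), "Bd", "D", SCHEME, FecundityMap(3.0))
        # payoffs vanish in the all-D state, so rates are the neutral ones
        assert d[0] == pytest.approx(1 - 1 / N)
        assert d.sum() == pytest.approx(1.0)

    def test_star_bd_all_producers_strong_selection_kills_leaves(self):
        d = death_rates(make_star(10), "Bd", "C", SCHEME, FecundityMap(20.0))
        assert d[1:].sum() == pytest.approx(1.0, abs=1e-9)
        assert d[0] == pytest.approx(0.0, abs=1e-9)


class TestInitialization:
    def test_uniform_star_masses_count_orbits(self):
        k = kernel_star_bd(10, SCHEME, FecundityMap(1.0))
        init = initialization(make_star(10), "Bd", SCHEME, FecundityMap(1.0), "uniform", k.space)
        assert init.mu_C[k.space.index((1, 0))] == pytest.approx(1 / 10)
        assert init.mu_C[k.space.index((0, 1))] == pytest.approx(9 / 10)

    def test_temperature_star_mutant_appears_at_hub(self):
        # in the all-D state a leaf reproduces with probability 1 - 1/N and
        # its offspring lands on the hub
        k = kernel_star_bd(10, SCHEME, FecundityMap(2.0))
        init = initialization(make_star(10), "Bd", SCHEME, FecundityMap(2.0), "temperature", k.space)
        assert init.mu_C[k.space.index((1, 0))] == pytest.approx(9 / 10)

    def test_temperature_equals_uniform_under_db(self):
        g = make_cycle(8)
        m = FecundityMap(1.7)
        t = initialization(g, "dB", SCHEME, m, "temperature")
        u = initialization(g, "dB", SCHEME, m, "uniform")
        assert np.allclose(t.mu_C, u.mu_C) and np.allclose(t.mu_D, u.mu_D)

    def test_closed_form_orbit_masses_match_generic_initialization(self):
        from prosofix.models import _star_orbit_masses

        for N in (10, 50):
            model = EvolutionModel("star", "Bd", SCHEME, N=N, init="temperature")
            m = FecundityMap(1.3)
            init = initialization(make_star(N), "Bd", SCHEME, m, "temperature")
            (wC_hub, wC_leaf), (wD_hub, wD_leaf) = _star_orbit_masses(model, 1.3)
            assert init.mu_C[0] == pytest.approx(wC_hub, abs=1e-12)
            assert init.mu_D[0] == pytest.approx(wD_hub, abs=1e-12)
            assert init.mu_D[1:].sum() == pytest.approx(wD_leaf, abs=1e-12)


class TestMeanFixation:
    def test_constant_profile_averages_to_itself(self):
        from prosofix import FixationResult

        k = kernel_cycle_db(6, SCHEME, FecundityMap(0.0))
        init = initialization(make_cycle(6), "dB", SCHEME, FecundityMap(0.0), "uniform", k.space)
        n = k.space.n_states
        fr = FixationResult(k.space, np.full(n, 0.37), np.full(n, 0.63))
        mc, md = mean_fixation(fr, init)
        assert mc == pytest.approx(0.37) and md == pytest.approx(0.63)

    @pytest.mark.parametrize(
        "model",
        [
            EvolutionModel("cycle", "dB", GoodsScheme("cf", 4, 1), N=8),
            EvolutionModel("star", "Bd", SCHEME, N=8, init="uniform"),
            EvolutionModel("star", "Bd", SCHEME, N=8, init="temperature"),
            EvolutionModel("cycle", "Bd", GoodsScheme("pp", 4, 1), N=6),
            EvolutionModel("star", "dB", GoodsScheme("cf", 5, 1), N=6, init="temperature"),
        ],
        ids=["cycle-dB", "star-unif", "star-temp", "cycle-Bd-full", "star-dB-full"],
    )
    def test_neutral_drift_is_type_symmetric(self, model):
        r = mean_rho(model, 0.0)
        assert r.rho_C == pytest.approx(r.rho_D, abs=1e-10)
        assert r.rho_C / (r.rho_C + r.rho_D) == pytest.approx(0.5, abs=1e-10)


class TestClosedFormStar:
    def test_neutral_conditioned_transition_is_one_over_N(self):
        # P~(1,0)->(1,1) = 1/(1 + (N-1) e^{d(b/(N-1)+c)}) equals 1/N at d=0
        N = 17
        rho_hub, _ = closed_form_star_ff(N, 5, 1, 0.0)
        assert rho_hub * (1 + (N - 2) * (N - 1) / N) * N == pytest.approx(1.0)

    @pytest.mark.parametrize("N", [5, 10, 25])
    @pytest.mark.parametrize("delta", [0.1, 1.0, 3.0])
    def test_matches_linear_solver(self, N, delta):
        k = kernel_star_bd(N, SCHEME, FecundityMap(delta))
        fr = solve_fixation(k)
        rho_hub, rho_leaf = closed_form_star_ff(N, 5, 1, delta)
        assert abs(fr.rho_C[k.space.index((1, 0))] - rho_hub) < 1e-9
        assert abs(fr.rho_C[k.space.index((0, 1))] - rho_leaf) < 1e-9

    @pytest.mark.parametrize("delta", [0.0, 0.5, 4.0])
    def test_ladder_profile_agrees_with_kernel_solver(self, delta):
        N = 12
        k = kernel_star_bd(N, SCHEME, FecundityMap(delta))
        fr = solve_fixation(k)
        prof = star_ff_profile(N, 5, 1, delta)
        idx = [prof.space.index(lab) for lab in k.space.labels]
        assert np.abs(prof.rho_C[idx] - fr.rho_C).max() < 1e-10

    def test_finite_for_huge_populations_and_selection(self):
        rho_hub, rho_leaf = closed_form_star_ff(5000, 5, 1, 50.0)
        assert np.isfinite(rho_hub) and np.isfinite(rho_leaf)
        assert 0 <= rho_hub <= 1 and 0 <= rho_leaf <= 1

    def test_fixation_vanishes_for_extreme_benefits(self):
        # beyond the crossover, raising b strictly lowers producer fixation
        vals = []
        for b in (20, 40, 80, 160, 320, 640):
            rho_hub, rho_leaf = closed_form_star_ff(50, b, 1, 1.0)
            vals.append((49 / 50) * rho_hub + (1 / 50) * rho_leaf)
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-6

    @given(st.integers(3, 50), st.floats(0.1, 15), st.floats(0.05, 10))
    def test_bernoulli_ordering_of_single_mutant_transitions(self, N, b, delta):
        """e^{db} - 1 > (N-1)(e^{db/(N-1)} - 1): reaching the two-mutant state
        is harder from a leaf than from the hub."""
        c = 1.0
        from_leaf = np.exp(-delta * c) / (np.exp(-delta * c) + np.exp(delta * b) + N - 2)
        from_hub = np.exp(-delta * c) / (
            np.exp(-delta * c) + (N - 1) * np.exp(delta * b / (N - 1))
        )
        assert np.exp(delta * b) - 1 > (N - 1) * (np.expm1(delta * b / (N - 1)))
        assert from_leaf < from_hub


class TestWeakSelectionMeanField:
    @pytest.mark.parametrize(
        "model_cf,model_ff",
        [
            (
                EvolutionModel("cycle", "dB", GoodsScheme("cf", 3, 1), N=6),
                EvolutionModel("cycle", "dB", GoodsScheme("ff", 3, 1), N=6),
            ),
            (
                EvolutionModel("star", "Bd", GoodsScheme("cf", 3, 1), N=6),
                EvolutionModel("star", "Bd", GoodsScheme("ff", 3, 1), N=6),
            ),
        ],
        ids=["cycle-dB", "star-Bd"],
    )
    def test_cf_and_ff_coincide_to_second_order(self, model_cf, model_ff):
        """Stochastic and mean-field goods differ only at O(delta^2)."""

        def gap(d):
            return abs(mean_rho(model_cf, d).rho_C - mean_rho(model_ff, d).rho_C)

        big, small = gap(0.1), gap(0.025)
        # a quadratic gap shrinks 16-fold when delta drops 4-fold
        assert small <= big / 8 + 1e-14
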