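"""Semi-Markov engine: simulation, GME inversion, Tauberian tails, sweeps."""

import math

import numpy as np
import pytest
from scipy import stats

from trpgating import (
    DwellLaw,
    GatingScheme,
    LaplaceInversionError,
    Trajectory,
    dwell_statistics,
    gme_occupancy,
    gme_occupancy_laplace,
    invert_laplace,
    master_equation_occupancy,
    mc_occupancy,
    sample_trajectory,
    tauberian_tail,
    temperature_rate_sweep,
)


class TestTrajectory:
    def test_fixed_seed_reproduces_bitwise(self, markov_scheme):
        a = sample_trajectory(markov_scheme, "C", 50.0, seed=7)
        b = sample_trajectory(markov_scheme, "C", 50.0, seed=7)
        assert a.states == b.states
        assert np.array_equal(a.durations, b.durations)

    def test_alternation_follows_chain(self, markov_scheme):
        traj = sample_trajectory(markov_scheme, "C", 100.0, seed=1)
        assert traj.states[0] == "C"
        assert all(s1 != s2 for s1, s2 in zip(traj.states, traj.states[1:]))

    def test_duration_shorter_than_first_dwell(self):
        slow = GatingScheme.two_state_markov(1e-6, 1e-6)
        traj = sample_trajectory(slow, "C", 0.001, seed=0)
        assert traj.n_dwells == 1
        assert traj.state_at(0.0005) == "C"

    def test_empirical_mean_within_3se(self):
        """10^5 exponential(5/s) dwells have mean within 3*SE of 0.2 s."""
        scheme = GatingScheme.two_state_markov(5.0, 5.0)
        traj = sample_trajectory(scheme, "C", 40_000.0, seed=11)
        d = traj.durations[:-1]
        assert d.size > 1e5
        se = d.std() / math.sqrt(d.size)
        assert abs(d.mean() - 0.2) < 3 * se

    def test_unknown_start_state_rejected(self, markov_scheme):
        with pytest.raises(KeyError):
            sample_trajectory(markov_scheme, "C1", 1.0, seed=0)

    def test_event_list_export(self, markov_scheme):
        df = sample_trajectory(markov_scheme, "C", 10.0, seed=3).to_frame()
        assert list(df.columns) == ["state", "duration_s"]
        assert (df["duration_s"] > 0).all()


class TestMcOccupancy:
    def test_initial_condition_is_indicator(self, markov_scheme, grid):
        curve = mc_occupancy(markov_scheme, "C", grid, n_traj=50, seed=0)
        assert curve.probs["C"][0] == 1.0
        assert curve.p_open[0] == 0.0

    def test_matches_master_equation_within_3se(self, markov_scheme, grid):
        curve = mc_occupancy(markov_scheme, "C", grid, n_traj=3000, seed=5)
        closed = master_equation_occupancy(2.0, 1.0, 0.0, grid)
        tol = 3 * np.maximum(curve.stderr["O"], 1e-3)
        assert np.all(np.abs(curve.p_open - closed.p_open) <= tol)

    def test_normalization_exact_for_fractions(self, gamma_scheme, grid):
        curve = mc_occupancy(gamma_scheme, "C", grid, n_traj=400, seed=2)
        total = sum(curve.probs.values())
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_renewal_reward_limit_gamma(self, gamma_scheme):
        """Long-time p_open -> <tau_O>/(<tau_O>+<tau_C>) = 0.2/0.7."""
        t_end = 35.0
        grid = np.array([0.0, t_end])
        curve = mc_occupancy(gamma_scheme, "C", grid, n_traj=4000, seed=9)
        target = 0.2 / 0.7
        assert abs(curve.p_open[-1] - target) <= 3 * max(curve.stderr["O"][-1], 1e-4)

    def test_bad_grid_rejected(self, markov_scheme):
        with pytest.raises(ValueError):
            mc_occupancy(markov_scheme, "C", np.array([]), 10, 0)
        with pytest.raises(ValueError):
            mc_occupancy(markov_scheme, "C", np.array([0.1, 0.5]), 10, 0)

    def test_three_state_occupancy_tracks_all_states(self):
        sch = GatingScheme.three_state(
            DwellLaw.exponential(4.0), DwellLaw.exponential(6.0), DwellLaw.exponential(2.0),
            branch_open_prob=0.6,
        )
        grid = np.concatenate(([0.0], np.geomspace(0.02, 5.0, 15)))
        curve = mc_occupancy(sch, "C1", grid, n_traj=500, seed=4)
        assert set(curve.probs) == {"C1", "C2", "O"}
        assert np.allclose(sum(curve.probs.values()), 1.0, atol=1e-12)


class TestMasterEquation:
    def test_initial_and_symmetric_limit(self, grid):
        curve = master_equation_occupancy(1.0, 1.0, 0.3, grid)
        assert curve.p_open[0] == pytest.approx(0.3)
        late = master_equation_occupancy(1.0, 1.0, 0.3, np.array([100.0]))
        assert late.p_open[0] == pytest.approx(0.5)

    def test_closed_form_value(self):
        curve = master_equation_occupancy(2.0, 1.0, 0.0, np.array([1.0]))
        assert curve.p_open[0] == pytest.approx((2.0 / 3.0) * (1.0 - math.exp(-3.0)), rel=1e-12)


class TestLaplaceInversion:
    @pytest.mark.parametrize(
        "fn,exact",
        [
            (lambda s: 1.0 / (s + 2.0), lambda t: np.exp(-2.0 * t)),
            (lambda s: 1.0 / s**2, lambda t: t),
            (lambda s: 1.0 / s, lambda t: np.ones_like(t)),
        ],
        ids=["exp_decay", "ramp", "step"],
    )
    @pytest.mark.parametrize("method", ["talbot", "stehfest"])
    def test_closed_form_validation_suite(self, fn, exact, method):
        t = np.geomspace(0.05, 5.0, 12)
        target = 1e-6 if method == "talbot" else 1e-3
        out = invert_laplace(fn, t, accuracy_target=target, method=method)
        assert np.allclose(out, exact(t), rtol=10 * target, atol=10 * target)

    def test_nonconvergence_reported_with_diagnostics(self):
        # a transform violating the talbot analyticity requirements
        noisy = lambda s: 1.0 / (s + 2.0) + 0.01 * np.sin(1e3 * abs(s))
        with pytest.raises(LaplaceInversionError, match="did not converge"):
            invert_laplace(noisy, np.array([1.0]), accuracy_target=1e-8)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            invert_laplace(lambda s: 1.0 / s, np.array([0.0]))


class TestGME:
    def test_markov_limit_matches_closed_form(self, markov_scheme, grid):
        gme = gme_occupancy(markov_scheme, "C", grid, accuracy_target=1e-6)
        closed = master_equation_occupancy(2.0, 1.0, 0.0, grid)
        assert np.allclose(gme.p_open, closed.p_open, atol=1e-6)

    def test_start_in_open_symmetric_formula(self, markov_scheme, grid):
        gme = gme_occupancy(markov_scheme, "O", grid, accuracy_target=1e-6)
        closed = master_equation_occupancy(2.0, 1.0, 1.0, grid)
        assert np.allclose(gme.p_open, closed.p_open, atol=1e-6)

    def test_final_value_theorem(self, markov_scheme):
        """s*P_O(s) -> lam_C/(lam_C+lam_O) = <tau_O>/(<tau_C>+<tau_O>) as s->0."""
        s = 1e-8
        val = s * gme_occupancy_laplace(markov_scheme, "C", s)
        assert val == pytest.approx(2.0 / 3.0, rel=1e-6)

    def test_gamma_laws_match_monte_carlo(self, gamma_scheme):
        grid = np.concatenate(([0.0], np.geomspace(0.05, 3.0, 10)))
        gme = gme_occupancy(gamma_scheme, "C", grid, accuracy_target=1e-6)
        mc = mc_occupancy(gamma_scheme, "C", grid, n_traj=4000, seed=21)
        tol = 3 * np.maximum(mc.stderr["O"], 1e-3)
        assert np.all(np.abs(gme.p_open - mc.p_open) <= tol)

    def test_nonpositive_s_rejected(self, markov_scheme):
        with pytest.raises(ValueError):
            gme_occupancy_laplace(markov_scheme, "C", 0.0)


class TestTauberian:
    def test_exponential_pair_is_markov_relaxation(self, markov_scheme):
        tail = tauberian_tail(markov_scheme)
        assert tail.regime == "exponential_relaxation"
        assert tail.rate == pytest.approx(3.0)

    def test_pareto_closed_law_gives_power_law_exponent(self):
        sch = GatingScheme.two_state(DwellLaw.pareto(0.5, 0.01), DwellLaw.exponential(10.0))
        tail = tauberian_tail(sch)
        assert tail.regime == "power_law"
        assert tail.exponent == pytest.approx(0.5)

    def test_unsupported_mix_flagged_not_silent(self, gamma_scheme):
        with pytest.raises(NotImplementedError):
            tauberian_tail(gamma_scheme)

    def test_mc_tail_slope_matches_exponent(self):
        """Log-log slope of empirical pareto survival ~ -alpha over 2 decades."""
        law = DwellLaw.pareto(0.5, 0.01)
        rng = np.random.default_rng(17)
        d = law.sample(rng, 100_000)
        t = np.geomspace(0.1, 10.0, 20)  # two decades, well above t_min
        surv = np.array([(d > ti).mean() for ti in t])
        slope = stats.linregress(np.log(t), np.log(surv)).slope
        assert abs(slope + 0.5) < 0.1


class TestDwellStatistics:
    def test_arithmetic_example(self):
        """C(2s) -> O(1s) -> C(4s) with a trailing censored dwell."""
        traj = Trajectory("C", ("C", "O", "C", "O"), np.array([2.0, 1.0, 4.0, 9.0]), 7.5)
        out = dwell_statistics(traj)
        assert out.loc["C", "mean_dwell_s"] == pytest.approx(3.0)
        assert out.loc["O", "mean_dwell_s"] == pytest.approx(1.0)
        assert out.loc["O", "n_events"] == 1  # censored final dwell excluded

    def test_missing_state_flagged_not_zero(self):
        traj = Trajectory("C", ("C", "O"), np.array([2.0, 5.0]), 4.0)
        out = dwell_statistics(traj)
        assert out.loc["O", "n_events"] == 0
        assert math.isnan(out.loc["O", "mean_dwell_s"])

    def test_effective_rate_within_3se(self):
        """10^5 exponential(10/s) dwells: 1/<tau> within 3*SE of 10/s."""
        scheme = GatingScheme.two_state_markov(10.0, 10.0)
        traj = sample_trajectory(scheme, "C", 11_000.0, seed=13)
        out = dwell_statistics(traj)
        n = out.loc["C", "n_events"]
        assert n > 5e4
        # delta method: SE of 1/<tau> for exponential dwells is rate/sqrt(n)
        assert abs(out.loc["C", "effective_rate_per_s"] - 10.0) < 3 * 10.0 / math.sqrt(n)


class TestTemperatureSweep:
    def test_analytic_matches_rate_constant(self, asymmetric_thermo, markov_scheme):
        T = np.linspace(280, 340, 7)
        table = temperature_rate_sweep(asymmetric_thermo, markov_scheme, T)
        from trpgating import rate_constant

        assert np.allclose(table["k_open_eff"], rate_constant(asymmetric_thermo, "open_transition", T))
        assert np.allclose(table["k_close_eff"], rate_constant(asymmetric_thermo, "close_transition", T))

    def test_asymmetry_preserved_at_every_temperature(self, asymmetric_thermo, markov_scheme):
        """Higher opening barrier -> opening slower than closing everywhere."""
        T = np.linspace(260, 390, 14)
        table = temperature_rate_sweep(asymmetric_thermo, markov_scheme, T)
        assert (table["k_open_eff"] < table["k_close_eff"]).all()

    def test_mc_estimates_agree_with_analytic(self, asymmetric_thermo, gamma_scheme):
        T = np.array([300.0, 320.0])
        analytic = temperature_rate_sweep(asymmetric_thermo, gamma_scheme, T)
        mc = temperature_rate_sweep(
            asymmetric_thermo, gamma_scheme, T, method="mc", n_traj=60, seed=3
        )
        # gamma shape 2: SE of the mean dwell ~ mean/sqrt(2 n); n ~ 50*60 events
        assert np.allclose(mc["k_open_eff"], analytic["k_open_eff"], rtol=0.05)
        assert np.allclose(mc["k_close_eff"], analytic["k_close_eff"], rtol=0.05)

    def test_temperature_range_enforced(self, asymmetric_thermo, markov_scheme):
        with pytest.raises(ValueError):
            temperature_rate_sweep(asymmetric_thermo, markov_scheme, [200.0])


def test_occupancy_frame_export(markov_scheme, grid):
    curve = mc_occupancy(markov_scheme, "C", grid, n_traj=100, seed=1)
    df = curve.to_frame()
    assert {"time_s", "p_open", "p_closed", "stderr_open"}.issubset(df.columns)
    assert np.allclose(df["p_open"] + df["p_closed"], 1.0)
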