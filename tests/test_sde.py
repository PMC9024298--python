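"""Stochastic stepping: scheme oracles, noise structure, path properties."""

import dataclasses
import math

import numpy as np
import pytest

from delaysir import (
    HistoryFunction,
    SimulationConfig,
    delta_cap,
    em_step,
    immunity_level,
    integrate_dde,
    milstein_step,
    simulate_ensemble,
    simulate_path,
)
from delaysir.sde import path_rng

STATE = (0.7, 0.4)
S_DELAY = 0.7
DT = 0.1

# one-step values computed with an independent transcription of the printed
# discrete scheme (f(0.7, 0.4) = 1.4768), frozen before the implementation
EM_ORACLE = {
    0.0: (0.6917874897590998, 0.3935839653304442),
    1.3: (0.6528157580316726, 0.43255569705787145),
    -0.7: (0.7127722683815606, 0.3725991867079834),
}
MILSTEIN_ORACLE = {
    0.0: (0.6941574789248636, 0.3912139761646804),
    1.3: (0.6511804655072956, 0.4341909895822485),
    -0.7: (0.7139809628561001, 0.3713904922334439),
}


class TestSteps:
    @pytest.mark.parametrize("xi", [0.0, 1.3, -0.7])
    def test_em_step_matches_hand_computation(self, sto_params, xi):
        s1, i1 = em_step(STATE, S_DELAY, xi, sto_params, DT)
        assert (s1, i1) == pytest.approx(EM_ORACLE[xi], rel=1e-14)

    @pytest.mark.parametrize("xi", [0.0, 1.3, -0.7])
    def test_milstein_step_matches_hand_computation(self, sto_params, xi):
        s1, i1 = milstein_step(STATE, S_DELAY, xi, sto_params, DT)
        assert (s1, i1) == pytest.approx(MILSTEIN_ORACLE[xi], rel=1e-14)

    @pytest.mark.parametrize("xi", [1.0, -1.0])
    def test_schemes_coincide_at_unit_draws(self, sto_params, xi):
        """The (xi^2 - 1) correction vanishes at xi = +-1."""
        assert milstein_step(STATE, S_DELAY, xi, sto_params, DT) == em_step(
            STATE, S_DELAY, xi, sto_params, DT
        )

    def test_noise_free_step_is_deterministic_euler(self, sto_params):
        quiet = dataclasses.replace(sto_params, sigma=0.0)
        for xi in (0.0, 2.0, -1.5):
            em = em_step(STATE, S_DELAY, xi, quiet, DT)
            mil = milstein_step(STATE, S_DELAY, xi, quiet, DT)
            assert em == mil
        # and matches an explicit Euler step of the drift
        s1, i1 = em_step(STATE, S_DELAY, 0.0, sto_params, DT)
        assert em == pytest.approx((s1, i1), rel=1e-14)

    @pytest.mark.parametrize("xi", [0.0, 0.5, 1.7, -2.3])
    def test_shared_noise_cancels_in_total(self, sto_params, xi):
        """S + I moves by drift only: the +-g noise terms cancel."""
        base_s, base_i = em_step(STATE, S_DELAY, 0.0, sto_params, DT)
        s1, i1 = em_step(STATE, S_DELAY, xi, sto_params, DT)
        assert s1 + i1 == pytest.approx(base_s + base_i, abs=1e-14)

    def test_milstein_correction_is_mean_zero(self, sto_params):
        """Averaged over xi ~ N(0,1), Milstein and EM steps agree."""
        rng = np.random.default_rng(20240917)
        xis = rng.standard_normal(100_000)
        em_i = np.array([em_step(STATE, S_DELAY, x, sto_params, DT)[1] for x in xis])
        mil_i = np.array(
            [milstein_step(STATE, S_DELAY, x, sto_params, DT)[1] for x in xis]
        )
        diff = mil_i - em_i
        se = diff.std(ddof=1) / math.sqrt(diff.size)
        assert abs(diff.mean()) < 3.0 * se


class TestPaths:
    @pytest.fixture
    def history(self):
        return HistoryFunction(s0=0.7, i0=0.4)

    def test_identical_seeds_bit_identical(self, sto_params, history):
        cfg = SimulationConfig(t_end=20.0, seed=5)
        a, _ = simulate_path(sto_params, history, cfg, 5)
        b, _ = simulate_path(sto_params, history, cfg, 5)
        assert np.array_equal(a.I, b.I) and np.array_equal(a.S, b.S)

    def test_noise_free_path_equals_deterministic_euler(self, sto_params, history):
        """sigma=0 reduces the scheme to forward Euler of the drift."""
        quiet = dataclasses.replace(sto_params, sigma=0.0)
        cfg = SimulationConfig(t_end=50.0)
        traj, clamped = simulate_path(quiet, history, cfg, 1)
        assert clamped == 0
        # manual forward Euler of the reduced system
        n = cfg.n_steps
        lag = cfg.delay_lag(quiet.omega)
        S = np.empty(n + 1)
        I = np.empty(n + 1)
        S[0], I[0] = history.s0, history.i0
        for k in range(n):
            sd = S[k - lag] if k >= lag else history.s0
            S[k + 1], I[k + 1] = em_step((S[k], I[k]), sd, 0.0, quiet, cfg.dt)
        assert np.array_equal(traj.S, S) and np.array_equal(traj.I, I)

    def test_recovered_is_one_minus_s_minus_i(self, sto_params, history):
        traj, _ = simulate_path(sto_params, history, SimulationConfig(t_end=20.0), 3)
        assert np.array_equal(traj.R, 1.0 - traj.S - traj.I)

    def test_off_grid_delay_rejected(self, sto_params, history):
        odd = dataclasses.replace(sto_params, omega=0.25)
        with pytest.raises(ValueError, match="not integral"):
            simulate_path(odd, history, SimulationConfig(dt=0.1, t_end=10.0), 0)

    def test_positivity_error_policy_reports_step(self, history):
        from delaysir import ModelParameters

        wild = ModelParameters(
            beta=0.4, b=0.3, p=0.5, m=0.2, gamma=0.2, omega=1.0, sigma=3.0
        )
        cfg = SimulationConfig(t_end=50.0, positivity_policy="error")
        with pytest.raises(RuntimeError, match="step"):
            # large noise without inhibition undershoots quickly on some seed
            for seed in range(20):
                simulate_path(wild, history, cfg, seed)

    def test_truncation_is_absorbing_for_infecteds(self, history):
        from delaysir import ModelParameters

        wild = ModelParameters(
            beta=0.4, b=0.3, p=0.5, m=0.2, gamma=0.2, omega=1.0, sigma=3.0
        )
        # EM lacks the quadratic-in-xi correction that shields I from
        # undershooting, so the boundary is actually reached
        cfg = SimulationConfig(t_end=50.0, scheme="euler_maruyama")
        for seed in range(20):
            traj, clamped = simulate_path(wild, history, cfg, seed)
            hit = np.flatnonzero(traj.I == 0.0)
            if hit.size:
                assert np.all(traj.I[hit[0]:] == 0.0)
                assert clamped > 0
                break
        else:
            pytest.fail("no path hit the zero boundary in 20 seeds")

    def test_extinction_scenario_paths_die_out(self, sto_params, history):
        """Sub-threshold noise regime: nearly all paths end near zero."""
        cfg = SimulationConfig(seed=0)
        low = sum(
            simulate_path(sto_params, history, cfg, path_rng(0, i))[0].I[-1] < 1e-3
            for i in range(50)
        )
        assert low >= 45

    def test_no_explosion_across_scenarios(self):
        from delaysir import builtin_scenarios

        for sc in builtin_scenarios().values():
            if sc.deterministic:
                continue
            cfg = dataclasses.replace(sc.config, n_realizations=5)
            ens = simulate_ensemble(sc.params, sc.history(), cfg)
            assert np.all(np.isfinite(ens.paths_I))
            assert np.all(ens.paths_I <= 1.0 + 1e-9)

    def test_invariant_region_rarely_exceeded(self, sto_params):
        """Starts inside the region stay there, up to discretization slack."""
        cap = delta_cap(sto_params)
        inside = HistoryFunction(s0=0.5, i0=0.2)
        assert inside.s0 + inside.i0 < cap
        cfg = SimulationConfig(seed=2)
        ens = simulate_ensemble(sto_params, inside, cfg)
        excess = 0
        total = 0
        for i in range(cfg.n_realizations):
            traj, _ = simulate_path(sto_params, inside, cfg, path_rng(2, i))
            excess += np.count_nonzero(traj.S + traj.I > cap + 0.02)
            total += traj.t.size
        assert excess / total < 0.01

    def test_schemes_converge_together_as_dt_shrinks(self, sto_params, history):
        """EM and the printed Milstein scheme agree in the dt -> 0 limit.

        Their pathwise gap is an accumulated mean-zero correction of size
        O(sqrt(dt)), so one halving shrinks it by ~sqrt(2) and the full
        0.1 -> 0.025 refinement by ~2.
        """
        gaps = []
        for dt in (0.1, 0.05, 0.025):
            trajs = {}
            for scheme in ("euler_maruyama", "milstein"):
                cfg = SimulationConfig(dt=dt, t_end=100.0, scheme=scheme)
                trajs[scheme], _ = simulate_path(sto_params, history, cfg, path_rng(11, 0))
            gaps.append(
                np.abs(trajs["euler_maruyama"].I - trajs["milstein"].I).max()
            )
        assert gaps[2] < gaps[1] < gaps[0]
        assert gaps[2] < 0.6 * gaps[0]


class TestEnsembles:
    @pytest.fixture
    def history(self):
        return HistoryFunction(s0=0.7, i0=0.4)

    def test_singleton_mean_is_the_path(self, sto_params, history):
        cfg = SimulationConfig(t_end=20.0, n_realizations=1, seed=9)
        ens = simulate_ensemble(sto_params, history, cfg)
        traj, _ = simulate_path(sto_params, history, cfg, path_rng(9, 0))
        assert np.array_equal(ens.mean_I, traj.I)
        assert np.array_equal(ens.mean_S, traj.S)

    def test_noise_free_mean_is_deterministic(self, sto_params, history):
        quiet = dataclasses.replace(sto_params, sigma=0.0)
        cfg = SimulationConfig(t_end=20.0, n_realizations=4)
        ens = simulate_ensemble(quiet, history, cfg)
        traj, _ = simulate_path(quiet, history, cfg, 0)
        assert np.allclose(ens.mean_I, traj.I, rtol=0, atol=1e-15)

    def test_persistent_scenario_tail_mean(self, persistent_params, history):
        """beta=0.8, sigma=0.2: mean infecteds settle above 0.9 I*."""
        ens = simulate_ensemble(persistent_params, history, SimulationConfig(seed=0))
        tail = ens.mean_I[ens.t >= 50.0]
        assert tail.mean() >= 0.9 * 0.118936

    def test_substream_independence(self, sto_params, history):
        """Terminal infecteds from disjoint seeds are uncorrelated."""
        cfg_a = SimulationConfig(seed=100)
        cfg_b = SimulationConfig(seed=200)
        term_a = simulate_ensemble(sto_params, history, cfg_a).tail_mean_I
        term_b = simulate_ensemble(sto_params, history, cfg_b).tail_mean_I
        corr = np.corrcoef(term_a, term_b)[0, 1]
        assert abs(corr) < 0.2

    def test_sidecar_metadata(self, sto_params, history, tmp_path):
        cfg = SimulationConfig(t_end=10.0, n_realizations=3, seed=4)
        ens = simulate_ensemble(sto_params, history, cfg)
        csv = tmp_path / "mean.csv"
        sidecar = tmp_path / "meta.json"
        ens.write(csv, sidecar)
        import json

        meta = json.loads(sidecar.read_text())
        assert meta == {
            "n_realizations": 3, "seed": 4, "scheme": "milstein",
            "dt": 0.1, "t_end": 10.0, "clamp_events": ens.clamp_events,
        }


class TestImmunityLevel:
    def test_no_vaccination_means_no_immunity(self, sto_params):
        history = HistoryFunction(s0=0.5, i0=0.2)
        quiet = dataclasses.replace(sto_params, sigma=0.0, m=1e-300)
        traj = integrate_dde(quiet, history, SimulationConfig(t_end=10.0))
        v = immunity_level(traj, history, quiet)
        assert np.abs(v).max() < 1e-12

    def test_constant_susceptibles_give_linear_growth(self, sto_params):
        """Trapezoid is exact on constants: V(t) = m s (1 - e^{-b w}) t."""
        from delaysir import Trajectory

        t = np.arange(0.0, 10.0 + 1e-9, 0.1)
        s_bar = 0.6
        traj = Trajectory(t=t, S=np.full_like(t, s_bar), I=np.zeros_like(t),
                          R=np.full_like(t, 1 - s_bar))
        history = HistoryFunction(s0=s_bar, i0=0.0)
        v = immunity_level(traj, history, sto_params)
        expected = (
            sto_params.m * s_bar
            * (1.0 - math.exp(-sto_params.b * sto_params.omega)) * t
        )
        assert np.allclose(v, expected, rtol=0, atol=1e-12)

    def test_longer_delay_raises_immunity(self, sto_params):
        """On constant S, a longer validity period means a higher level."""
        from delaysir import Trajectory

        t = np.arange(0.0, 10.0 + 1e-9, 0.1)
        traj = Trajectory(t=t, S=np.full_like(t, 0.6), I=np.zeros_like(t),
                          R=np.full_like(t, 0.4))
        history = HistoryFunction(s0=0.6, i0=0.0)
        levels = []
        for omega in (1.0, 2.0, 3.0):
            params = dataclasses.replace(sto_params, omega=omega)
            levels.append(immunity_level(traj, history, params))
        assert np.all(levels[1][1:] > levels[0][1:])
        assert np.all(levels[2][1:] > levels[1][1:])
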