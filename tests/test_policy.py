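import dataclasses
import itertools

import numpy as np
import pytest
from scipy.stats import norm

import valuedp as vd
from valuedp.errors import CalibrationError, ConfigError
from valuedp.policy import (
    WAIT,
    bellman_step,
    estimate_grid,
    expected_continuation,
    terminal_values,
)

from conftest import make_stub_policy


def dp_oracle(cfg, rho=0.0):
    """Exhaustive small-instance solution by direct 3-D quadrature recursion.

    Evaluates the stop/continue tree slice by slice with explicitly formed
    product weights at every grid point — no separable smoothing, no shared
    code with the solver's backward induction.
    """
    grid = np.linspace(cfg.grid_lo, cfg.grid_hi, cfg.grid_n)
    times = cfg.times()
    b = cfg.belief()
    n = cfg.grid_n

    def stop_rewards(t):
        if cfg.reward_mode == "expected":
            return np.array([cfg.utility.expected(float(g), b.posterior_var(t)) for g in grid])
        return np.array([cfg.utility.evaluate(float(g)) for g in grid])

    rT = stop_rewards(times[-1])
    V = np.empty((n, n, n))
    A = np.empty((n, n, n), dtype=int)
    for i, j, k in itertools.product(range(n), repeat=3):
        rs = (rT[i], rT[j], rT[k])
        V[i, j, k] = max(rs)
        A[i, j, k] = int(np.argmax(rs))
    if cfg.cost_regime == "linear":
        V -= rho * cfg.t_w

    for t in times[-2::-1]:
        s = np.sqrt(max(b.posterior_var(t) - b.posterior_var(t + cfg.dt), 0.0))
        K = norm.pdf((grid[None, :] - grid[:, None]) / s)
        K = K / K.sum(axis=1, keepdims=True)
        r = stop_rewards(t)
        V_new = np.empty_like(V)
        A_new = np.empty_like(A)
        for i, j, k in itertools.product(range(n), repeat=3):
            w = K[i][:, None, None] * K[j][None, :, None] * K[k][None, None, :]
            ev = float(np.sum(w * V))
            rs = (r[i], r[j], r[k])
            if cfg.cost_regime == "linear":
                stop = max(rs) - rho * cfg.t_w
                cont = ev - (cfg.c + rho) * cfg.dt
            else:
                stop = max(rs)
                cont = ev * cfg.gamma**cfg.dt
            if cont > stop:
                V_new[i, j, k] = cont
                A_new[i, j, k] = WAIT
            else:
                V_new[i, j, k] = stop
                A_new[i, j, k] = int(np.argmax(rs))
        V, A = V_new, A_new
    return V, A


def tiny_cfg(**kw):
    base = dict(
        cost_regime="geometric",
        gamma=0.3,
        utility=vd.logistic_utility(4.0, 1.0),
        grid_n=5,
        dt=0.2,
        horizon=0.6,
    )
    base.update(kw)
    return vd.BellmanConfig(**base)


class TestTerminalValues:
    def test_argmax_of_linear_utility(self):
        cfg = tiny_cfg(utility=vd.linear_utility(), grid_n=11, reward_mode="mean")
        V, A = terminal_values(cfg)
        g = estimate_grid(cfg)
        i1, i0, im1 = [int(np.where(g == x)[0][0]) for x in (1.0, 0.0, -1.0)]
        assert V[i1, i0, im1] == pytest.approx(1.0)
        assert A[i1, i0, im1] == 0

    def test_equal_triple_takes_common_utility(self):
        u = vd.logistic_utility(4.0, 3.5)
        cfg = tiny_cfg(utility=u, grid_n=41, grid_lo=-5.0, grid_hi=5.0, reward_mode="mean")
        V, A = terminal_values(cfg)
        g = estimate_grid(cfg)
        iv = int(np.where(np.isclose(g, 1.5))[0][0])
        assert V[iv, iv, iv] == pytest.approx(u.evaluate(1.5))
        assert A[iv, iv, iv] == 0  # tie resolves to the lowest index

    def test_best_single_option(self):
        cfg = tiny_cfg(utility=vd.logistic_utility(4.0, 3.5), grid_n=41,
                       grid_lo=-5.0, grid_hi=5.0, reward_mode="mean")
        V, _ = terminal_values(cfg)
        g = estimate_grid(cfg)
        iv = int(np.where(np.isclose(g, 1.5))[0][0])
        i0 = int(np.where(np.isclose(g, 0.0))[0][0])
        assert V[iv, i0, i0] == pytest.approx(3.9582389944515327, abs=1e-10)


class TestExpectedContinuation:
    def test_constant_field_preserved(self):
        cfg = tiny_cfg()
        V = np.full((5, 5, 5), 3.25)
        out = expected_continuation(V, 1.0, cfg)
        assert np.allclose(out, 3.25, atol=1e-12)

    def test_zero_std_is_identity(self):
        cfg = tiny_cfg()
        rng = np.random.default_rng(0)
        V = rng.normal(size=(5, 5, 5))
        assert np.array_equal(expected_continuation(V, 0.0, cfg), V)

    def test_matches_direct_quadrature(self):
        cfg = tiny_cfg()
        grid = estimate_grid(cfg)
        h = grid[1] - grid[0]
        rng = np.random.default_rng(1)
        V = rng.normal(size=(5, 5, 5))
        out = expected_continuation(V, h, cfg)
        K = norm.pdf((grid[None, :] - grid[:, None]) / h)
        K = K / K.sum(axis=1, keepdims=True)
        for i, j, k in itertools.product(range(5), repeat=3):
            w = K[i][:, None, None] * K[j][None, :, None] * K[k][None, None, :]
            assert out[i, j, k] == pytest.approx(float(np.sum(w * V)), rel=1e-6)

    def test_nonfinite_std_rejected(self):
        with pytest.raises(ValueError):
            expected_continuation(np.zeros((5, 5, 5)), np.nan, tiny_cfg())


class TestBellmanStep:
    def test_vanishing_discount_decides_everywhere(self):
        # on a positive-value grid every stop reward is positive, so a
        # discount factor near zero annihilates any continuation advantage
        cfg = tiny_cfg(gamma=1e-12, dt=1.0, horizon=2.0, grid_lo=0.5, grid_hi=5.0)
        V_next, _ = terminal_values(cfg)
        _, A, M = bellman_step(V_next, 0.0, cfg)
        assert not np.any(A == WAIT)
        assert np.all(M <= 0)

    def test_free_waiting_never_worse_than_stopping(self):
        cfg = tiny_cfg(cost_regime="linear", gamma=None, c=0.0, rho=0.0)
        V_next, _ = terminal_values(cfg, rho=0.0)
        V, _, _ = bellman_step(V_next, 0.0, cfg, rho=0.0)
        g = estimate_grid(cfg)
        b = cfg.belief()
        r = np.array([cfg.utility.expected(float(x), b.posterior_var(0.0)) for x in g])
        stop = np.maximum.reduce(np.meshgrid(r, r, r, indexing="ij"))
        assert np.all(V >= stop - 1e-12)


class TestSolvePolicy:
    @pytest.mark.parametrize("regime", ["geometric", "linear"])
    def test_small_instance_matches_exhaustive_oracle(self, regime):
        """5^3 grid, 3 backward steps: DP equals direct stop/continue enumeration."""
        if regime == "geometric":
            cfg = tiny_cfg()
            rho = 0.0
        else:
            cfg = tiny_cfg(cost_regime="linear", gamma=None, c=0.1, rho=0.8)
            rho = 0.8
        p = vd.solve_policy(cfg)
        V_o, A_o = dp_oracle(cfg, rho)
        assert np.max(np.abs(p.values[0] - V_o)) < 1e-6
        assert np.array_equal(p.actions[0], A_o)

    def test_permutation_equivariance(self, small_geometric_cfg):
        p = vd.solve_policy(small_geometric_cfg)
        perm = (2, 0, 1)  # option i of the permuted problem is option perm[i] here
        for k in (0, len(p.times) // 2):
            V, A = p.values[k], p.actions[k]
            V_p = np.transpose(V, perm)
            A_t = np.transpose(A, perm)
            assert np.allclose(V, V_p, atol=1e-10)  # shared priors: V symmetric
            relabel = {WAIT: WAIT, 0: perm.index(0), 1: perm.index(1), 2: perm.index(2)}
            A_p = np.vectorize(relabel.get)(A_t)
            grid = estimate_grid(small_geometric_cfg)
            X = np.meshgrid(grid, grid, grid, indexing="ij")
            ties = (X[0] == X[1]) | (X[1] == X[2]) | (X[0] == X[2])
            assert np.array_equal(A[~ties], A_p[~ties])

    def test_no_wait_at_final_slice(self, small_geometric_cfg):
        p = vd.solve_policy(small_geometric_cfg)
        assert not np.any(p.actions[-1] == WAIT)

    def test_value_monotone_in_each_coordinate(self, small_geometric_cfg):
        p = vd.solve_policy(small_geometric_cfg)
        for k in range(len(p.times)):
            for ax in range(3):
                assert np.all(np.diff(p.values[k], axis=ax) >= -1e-10)

    def test_value_equals_stop_reward_exactly_on_decide_region(self, small_geometric_cfg):
        cfg = small_geometric_cfg
        p = vd.solve_policy(cfg)
        g = estimate_grid(cfg)
        b = cfg.belief()
        for k in (0, 2):
            r = np.asarray(cfg.utility.expected(g, b.posterior_var(p.times[k])))
            stop = np.maximum.reduce(np.meshgrid(r, r, r, indexing="ij"))
            decide = p.actions[k] != WAIT
            assert np.allclose(p.values[k][decide], stop[decide], atol=1e-12)
            assert np.all(p.values[k][~decide] > stop[~decide])

    def test_geometric_wait_region_collapses_over_time(self, geometric02_policy):
        p = geometric02_policy
        for v in (-2.0, 0.0):
            areas = [vd.project_boundary_slice(p, t, v).wait_area() for t in (0.0, 1.0, 2.0)]
            assert areas[0] >= areas[1] >= areas[2]
            assert areas[0] > areas[2] or areas[0] == 0

    def test_linear_utility_boundary_independent_of_magnitude(self, linear_linear_policy):
        """Bayes Risk + linear utility: boundary geometry is translation-invariant.

        The projected wait region's radial extent should agree across
        equal-value planes to within one grid spacing.
        """
        p = linear_linear_policy
        h = (p.config.grid_hi - p.config.grid_lo) / (p.config.grid_n - 1)
        for t in (0.0, 1.0):
            radii = []
            for v in (-2.0, -1.0, 0.0, 1.0, 2.0):
                tab = vd.project_boundary_slice(p, t, v).table
                decide = tab[tab["action"] != "wait"]
                assert len(decide) > 0
                # inner radius of the decide region, i.e. distance of the
                # boundary from the equal-value diagonal
                radii.append(np.hypot(decide["u"], decide["w"]).min())
            assert max(radii) - min(radii) <= h * np.sqrt(2) + 1e-9


class TestCalibration:
    def test_zero_utility_gives_zero_rate(self):
        class ZeroUtility:
            family = "custom"
            m = None
            s = None

            def evaluate(self, x):
                return np.zeros_like(np.asarray(x, dtype=float))

            def expected(self, mean, var):
                return np.zeros_like(np.asarray(mean, dtype=float))

        cfg = tiny_cfg(cost_regime="linear", gamma=None, utility=ZeroUtility())
        assert vd.calibrate_reward_rate(cfg) == 0.0

    def test_fixed_point_residual_below_tolerance(self):
        cfg = vd.BellmanConfig(
            cost_regime="linear",
            c=0.0,
            utility=vd.logistic_utility(4.0, 0.25),
            grid_n=21,
            dt=0.1,
            horizon=2.0,
        )
        rho = vd.calibrate_reward_rate(cfg)
        assert 0.0 < rho < 4.0 / cfg.t_w
        p = vd.solve_policy(dataclasses.replace(cfg, rho=rho))
        assert abs(p.value_at(0.0, (1.5, 1.5, 1.5))) < 1e-3

    def test_geometric_regime_rejected(self):
        with pytest.raises(ConfigError):
            vd.calibrate_reward_rate(tiny_cfg())


class TestBoundarySlice:
    def test_decide_everywhere_policy_has_no_wait_labels(self, small_geometric_cfg):
        p = make_stub_policy(small_geometric_cfg, margin_value=-1.0)
        sl = vd.project_boundary_slice(p, 0.0, 0.0)
        assert sl.n_points > 0
        assert sl.wait_area() == 0
        assert set(sl.table["action"]) <= {"choose_1", "choose_2", "choose_3"}

    def test_threefold_rotation_symmetry(self, geometric02_policy):
        """Cyclically relabeling options permutes choose labels, so off the
        tie set the three labels appear in equal numbers on any equal-value
        plane."""
        tab = vd.project_boundary_slice(geometric02_policy, 0.5, -1.0).table
        # pairwise-equal coordinates map to the lines u=0 and w = +-u/sqrt(3)
        ties = (
            np.isclose(tab["u"], 0.0, atol=1e-9)
            | np.isclose(tab["w"], tab["u"] / np.sqrt(3), atol=1e-9)
            | np.isclose(tab["w"], -tab["u"] / np.sqrt(3), atol=1e-9)
        )
        counts = tab[~ties]["action"].value_counts()
        assert counts.get("choose_1", 0) == counts.get("choose_2", 0) == counts.get("choose_3", 0)

    def test_wait_area_larger_at_low_magnitude(self, geometric02_policy):
        lo = vd.project_boundary_slice(geometric02_policy, 0.5, -2.0)
        hi = vd.project_boundary_slice(geometric02_policy, 0.5, 2.0)
        assert lo.wait_area() > hi.wait_area()

    def test_plane_outside_grid_rejected(self, small_geometric_cfg):
        p = vd.solve_policy(small_geometric_cfg)
        with pytest.raises(ValueError):
            vd.project_boundary_slice(p, 0.0, 7.0)

    def test_unknown_time_slice_rejected(self, small_geometric_cfg):
        p = vd.solve_policy(small_geometric_cfg)
        with pytest.raises(ValueError):
            vd.project_boundary_slice(p, 0.123, 0.0)


class TestConfigValidation:
    def test_gamma_required_for_geometric(self):
        with pytest.raises(ConfigError):
            vd.BellmanConfig(cost_regime="geometric")

    def test_gamma_range_enforced(self):
        with pytest.raises(ConfigError):
            vd.BellmanConfig(cost_regime="geometric", gamma=1.5)

    def test_gamma_meaningless_in_linear_regime(self):
        with pytest.raises(ConfigError):
            vd.BellmanConfig(cost_regime="linear", gamma=0.5)

    def test_horizon_must_be_multiple_of_dt(self):
        with pytest.raises(ConfigError):
            vd.BellmanConfig(cost_regime="geometric", gamma=0.5, dt=0.07, horizon=1.0)

    def test_missing_rho_raises_only_at_solve_time_via_calibration(self):
        cfg = tiny_cfg(cost_regime="linear", gamma=None)
        p = vd.solve_policy(cfg)  # calibrates automatically
        assert p.rho is not None and p.rho > 0
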