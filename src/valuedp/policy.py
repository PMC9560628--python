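"""Optimal stopping policies by backward induction on the estimate grid.

The decision-maker tracks a posterior-mean estimate x̂_i for each option and
at every instant either stops (collecting the subjective reward of the best
option) or pays for more evidence. Two Bellman formulations are solved on a
regular 3-D grid of estimates:

linear (Bayes Risk), with cost c per unit time, reward rate ρ and
inter-trial wait t_w::

    V(t, x̂) = max( max_i r_i(x̂) - ρ t_w,  <V(t+δt, x̂(t+δt))> - (c+ρ) δt )

geometric discounting, with per-unit-time discount factor γ in (0, 1)::

    V(t, x̂) = max( max_i r_i(x̂),  <V(t+δt, x̂(t+δt))> γ^δt )

The expectation <·> is over the one-step law of the posterior means: each
coordinate independently gains Gaussian diffusion with the time-dependent
standard deviation given by the drop in posterior variance (see
:mod:`valuedp.belief`), implemented as separable Gaussian smoothing with
kernel mass renormalized at the grid edges. Backward induction runs from a
forced-choice horizon T down to t = 0 and records, per time slice, the value
function, the greedy action, and the signed margin (continuation minus stop
value) whose zero crossing is the decision boundary.

In the linear regime the reward rate ρ is, if not supplied, calibrated to
the self-consistent fixed point at which the value of starting a trial from
the prior is zero — the standard construction for reward-rate-optimal
sequential sampling over an indefinite run of trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .belief import GaussianBelief
from .errors import CalibrationError, ConfigError, NumericalError
from .utility import UtilityFunction

__all__ = [
    "BellmanConfig",
    "PolicyGrid",
    "BoundarySlice",
    "WAIT",
    "estimate_grid",
    "terminal_values",
    "expected_continuation",
    "bellman_step",
    "solve_policy",
    "calibrate_reward_rate",
    "project_boundary_slice",
]

WAIT = -1  # action code for "continue sampling"; options are 0..n_options-1

_SMOOTH_EPS = 1e-12  # transition std below which smoothing is the identity


@dataclass(frozen=True)
class BellmanConfig:
    """All inputs of the dynamic program.

    Defaults follow the parameterisation used throughout the published
    analyses: Gaussian prior Normal(1.5, 5) on each option's value,
    observation noise variance 2, inter-trial wait t_w = 1, and an estimate
    grid on [-5, 5]^3 (prior mass beyond ±5 is negligible for these
    parameters). The horizon is a numerical device: the transition std
    decays like 1/t, so boundaries freeze and results are insensitive to T
    beyond ~2 time units here.
    """

    cost_regime: str  # "linear" | "geometric"
    utility: UtilityFunction = field(default_factory=UtilityFunction)
    n_options: int = 3
    prior_mean: float = 1.5
    prior_var: float = 5.0
    obs_var: float = 2.0
    c: float = 0.0
    rho: float | None = None
    t_w: float = 1.0
    gamma: float | None = None
    dt: float = 0.05
    horizon: float = 3.0
    grid_lo: float = -5.0
    grid_hi: float = 5.0
    grid_n: int = 41
    reward_mode: str = "expected"  # "expected": r_i = E[U(X_i)|belief]; "mean": r_i = U(x̂_i)

    def __post_init__(self) -> None:
        if self.cost_regime not in ("linear", "geometric"):
            raise ConfigError(f"unknown cost regime {self.cost_regime!r}")
        if self.cost_regime == "geometric":
            if self.gamma is None:
                raise ConfigError("geometric regime requires a discount factor gamma")
            if not 0.0 < self.gamma < 1.0:
                raise ConfigError(f"gamma must lie in (0, 1), got {self.gamma}")
        else:
            if self.gamma is not None:
                raise ConfigError("gamma is meaningless in the linear regime")
            if self.c < 0:
                raise ConfigError("linear time cost c must be nonnegative")
            if self.t_w <= 0:
                raise ConfigError("inter-trial wait t_w must be positive")
        if self.n_options not in (2, 3):
            raise ConfigError("n_options must be 2 or 3")
        if not self.grid_lo < self.grid_hi:
            raise ConfigError("grid_lo must be below grid_hi")
        if self.grid_n < 3:
            raise ConfigError("grid_n must be at least 3")
        if self.dt <= 0 or self.horizon <= 0:
            raise ConfigError("dt and horizon must be positive")
        n_steps = self.horizon / self.dt
        if abs(n_steps - round(n_steps)) > 1e-8:
            raise ConfigError("horizon must be an integer multiple of dt")
        if self.reward_mode not in ("mean", "expected"):
            raise ConfigError(f"unknown reward_mode {self.reward_mode!r}")
        if not hasattr(self.utility, "evaluate"):
            raise ConfigError("utility must provide an evaluate(x) method")
        GaussianBelief(self.prior_mean, self.prior_var, self.obs_var)  # validates

    @property
    def n_slices(self) -> int:
        return int(round(self.horizon / self.dt)) + 1

    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.horizon, self.n_slices)

    def belief(self) -> GaussianBelief:
        return GaussianBelief(self.prior_mean, self.prior_var, self.obs_var)


def estimate_grid(cfg: BellmanConfig) -> np.ndarray:
    """The common 1-D axis of the estimate grid."""
    return np.linspace(cfg.grid_lo, cfg.grid_hi, cfg.grid_n)


def _stop_rewards(cfg: BellmanConfig, grid: np.ndarray, t: float) -> np.ndarray:
    """Per-axis reward of stopping for an option whose estimate is g.

    In the default ``"expected"`` mode the reward of choosing option i is
    the posterior expectation of its utility, which depends on t through
    the posterior variance — this is what gives the stop reward its
    explicit time dependence in the Bellman recursion, and with a bounded
    (logistic) utility it is what allows the geometric policy to wait at
    all when the posterior-mean utility is already near the cap. The
    ``"mean"`` mode instead takes the utility of the posterior-mean
    estimate directly.
    """
    if cfg.reward_mode == "mean":
        return np.asarray(cfg.utility.evaluate(grid), dtype=float)
    var = cfg.belief().posterior_var(t)
    return np.asarray(cfg.utility.expected(grid, var), dtype=float)


def _stop_value_action(r1d: np.ndarray, n_options: int) -> tuple[np.ndarray, np.ndarray]:
    """max_i r_i and the argmax (lowest index on ties) on the full grid."""
    n = r1d.size
    best = np.full((n,) * n_options, -np.inf)
    action = np.zeros((n,) * n_options, dtype=np.int8)
    for i in range(n_options):
        shape = [1] * n_options
        shape[i] = n
        ri = r1d.reshape(shape)
        better = ri > best
        best = np.where(better, ri, best)
        action = np.where(better, np.int8(i), action)
    return best, action


def terminal_values(cfg: BellmanConfig, rho: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Forced-choice seed of the backward induction at the horizon.

    Returns ``(V_T, A_T)``: the best immediate reward (minus ρ t_w in the
    linear regime) and the chosen option everywhere — waiting is not
    available at the horizon.
    """
    grid = estimate_grid(cfg)
    r1d = _stop_rewards(cfg, grid, cfg.horizon)
    V, A = _stop_value_action(r1d, cfg.n_options)
    if cfg.cost_regime == "linear":
        V = V - _resolve_rho(cfg, rho) * cfg.t_w
    return V, A


def _resolve_rho(cfg: BellmanConfig, rho: float | None) -> float:
    if cfg.cost_regime != "linear":
        return 0.0
    if rho is not None:
        return rho
    if cfg.rho is None:
        raise ConfigError("linear regime requires rho (supply it or calibrate first)")
    return cfg.rho


def _transition_matrix(grid: np.ndarray, s: float) -> np.ndarray:
    """Row-stochastic Gaussian step kernel on the 1-D grid.

    Row i holds the probabilities that an estimate at grid[i] moves to each
    node after one step of diffusion with std ``s``; rows are renormalized
    so that probability mass falling beyond the grid edges is reflected back
    onto the boundary region rather than lost.
    """
    if s < _SMOOTH_EPS:
        return np.eye(grid.size)
    d = (grid[None, :] - grid[:, None]) / s
    K = np.exp(-0.5 * d * d)
    return K / K.sum(axis=1, keepdims=True)


def expected_continuation(V_next: np.ndarray, s_t: float, cfg: BellmanConfig) -> np.ndarray:
    """<V(t+δt, x̂(t+δt))>: Gaussian smoothing of the next slice.

    The posterior means of the options diffuse independently, so the
    expectation factorizes into one 1-D Gaussian convolution per axis with
    common std ``s_t``.
    """
    if not np.isfinite(s_t) or s_t < 0:
        raise ValueError(f"transition std must be finite and nonnegative, got {s_t}")
    if s_t < _SMOOTH_EPS:
        return V_next.copy()
    grid = estimate_grid(cfg)
    K = _transition_matrix(grid, s_t)
    V = V_next
    for _ in range(cfg.n_options):
        # consume axis 0, append the smoothed axis at the end; after
        # n_options applications the axis order is restored
        V = np.tensordot(V, K, axes=([0], [1]))
    return V


def bellman_step(
    V_next: np.ndarray, t: float, cfg: BellmanConfig, rho: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One backward-induction step from slice t+δt to slice t.

    Returns ``(V_t, A_t, M_t)`` where ``M_t`` is the signed margin
    (continuation value minus stop value); the policy waits exactly where
    ``M_t > 0``, so its zero level set is the decision boundary.
    """
    grid = estimate_grid(cfg)
    s_t = cfg.belief().posterior_var(t) - cfg.belief().posterior_var(t + cfg.dt)
    s_t = math.sqrt(max(s_t, 0.0))
    EV = expected_continuation(V_next, s_t, cfg)

    r1d = _stop_rewards(cfg, grid, t)
    stop, choose = _stop_value_action(r1d, cfg.n_options)
    if cfg.cost_regime == "linear":
        rho_v = _resolve_rho(cfg, rho)
        stop = stop - rho_v * cfg.t_w
        cont = EV - (cfg.c + rho_v) * cfg.dt
    else:
        cont = EV * cfg.gamma**cfg.dt

    margin = cont - stop
    wait = margin > 0.0  # ties resolve to deciding
    V_t = np.where(wait, cont, stop)
    A_t = np.where(wait, np.int8(WAIT), choose)
    return V_t, A_t, margin


@dataclass
class PolicyGrid:
    """Solved policy: per-time-slice values, actions and stop/continue margins.

    ``actions`` holds ``WAIT`` (-1) on the continuation region and the
    chosen option index elsewhere (lowest index on exact ties; simulation
    re-breaks ties uniformly at run time). ``margin`` is continuation minus
    stop value, positive exactly on the wait region, and is what the
    simulator interpolates.
    """

    times: np.ndarray
    values: np.ndarray  # (n_slices, grid_n, ..., grid_n)
    actions: np.ndarray  # int8, same shape
    margin: np.ndarray  # same shape
    config: BellmanConfig
    rho: float | None = None  # resolved reward rate (linear regime)

    def slice_index(self, t: float) -> int:
        idx = int(np.argmin(np.abs(self.times - t)))
        if not math.isclose(self.times[idx], t, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"t={t} is not a policy time slice")
        return idx

    def nearest_slice(self, t: float) -> int:
        """Index of the time slice closest to ``t`` (for simulation lookups)."""
        return int(np.argmin(np.abs(self.times - t)))

    def value_at(self, t: float, point) -> float:
        """Trilinear interpolation of the value function at one estimate point."""
        grid = estimate_grid(self.config)
        k = self.slice_index(t)
        itp = RegularGridInterpolator((grid,) * self.config.n_options, self.values[k])
        return float(itp(np.atleast_2d(point))[0])

    def margin_interpolator(self, k: int) -> RegularGridInterpolator:
        grid = estimate_grid(self.config)
        return RegularGridInterpolator((grid,) * self.config.n_options, self.margin[k])


def solve_policy(cfg: BellmanConfig) -> PolicyGrid:
    """Full backward induction from the horizon to t = 0.

    Deterministic given the configuration. In the linear regime with no
    reward rate supplied, ρ is calibrated first (see
    :func:`calibrate_reward_rate`).
    """
    rho: float | None = None
    if cfg.cost_regime == "linear":
        rho = cfg.rho if cfg.rho is not None else calibrate_reward_rate(cfg)

    times = cfg.times()
    nt = times.size
    shape = (cfg.grid_n,) * cfg.n_options
    values = np.empty((nt,) + shape)
    actions = np.empty((nt,) + shape, dtype=np.int8)
    margin = np.empty((nt,) + shape)

    V_T, A_T = terminal_values(cfg, rho)
    values[-1], actions[-1] = V_T, A_T
    margin[-1] = 0.0  # waiting unavailable at the horizon; boundary collapses onto it

    for k in range(nt - 2, -1, -1):
        V_t, A_t, M_t = bellman_step(values[k + 1], times[k], cfg, rho)
        if not np.all(np.isfinite(V_t)):
            raise NumericalError(f"non-finite values at time slice {k} (t={times[k]:g})")
        values[k], actions[k], margin[k] = V_t, A_t, M_t

    return PolicyGrid(times=times, values=values, actions=actions, margin=margin, config=cfg, rho=rho)


def _value_at_prior(cfg: BellmanConfig, rho: float) -> float:
    """V(0, (x̄_p, ..., x̄_p)) by a storage-light backward pass at fixed ρ."""
    times = cfg.times()
    V, _ = terminal_values(cfg, rho)
    for k in range(times.size - 2, -1, -1):
        V, _, _ = bellman_step(V, times[k], cfg, rho)
    grid = estimate_grid(cfg)
    itp = RegularGridInterpolator((grid,) * cfg.n_options, V)
    point = np.full(cfg.n_options, cfg.prior_mean)
    return float(itp(point[None, :])[0])


def calibrate_reward_rate(cfg: BellmanConfig, tol: float = 1e-3, max_iter: int = 60) -> float:
    """Self-consistent reward rate ρ* for the linear (Bayes Risk) regime.

    Over an indefinite sequence of trials the optimal long-run reward rate
    makes the net value of starting a fresh trial zero: bisection on
    ρ ∈ (0, max U / t_w) drives |V_ρ(0, prior point)| below ``tol``. The
    residual at the prior point directly bounds the policy error where
    trials actually start.
    """
    if cfg.cost_regime != "linear":
        raise ConfigError("reward-rate calibration applies to the linear regime only")
    grid = estimate_grid(cfg)
    u_max = float(np.max(_stop_rewards(cfg, grid, 0.0)))
    if u_max <= 0.0:
        return 0.0

    lo, hi = 1e-6, u_max / cfg.t_w
    f_lo = _value_at_prior(cfg, lo)
    f_hi = _value_at_prior(cfg, hi)
    if f_lo <= 0.0 or f_hi >= 0.0:
        raise CalibrationError(
            f"no sign change on bracket: V(0)={f_lo:.6g} at rho={lo:.6g}, "
            f"V(0)={f_hi:.6g} at rho={hi:.6g}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _value_at_prior(cfg, mid)
        if abs(f_mid) < tol:
            return mid
        if f_mid > 0.0:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(f"bisection did not converge: bracket ({lo:.6g}, {hi:.6g})")


# --------------------------------------------------------------------------
# Boundary-triangle projections


_ACTION_NAMES = {WAIT: "wait", 0: "choose_1", 1: "choose_2", 2: "choose_3"}

# orthonormal basis of the plane x1+x2+x3 = const
_U_BASIS = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
_W_BASIS = np.array([1.0, 1.0, -2.0]) / np.sqrt(6.0)


@dataclass
class BoundarySlice:
    """A planar cut of the policy orthogonal to the equal-value diagonal.

    Grid points within half a grid spacing of the plane x̂1+x̂2+x̂3 = 3v,
    mapped to 2-D coordinates (u, w) in the plane, each carrying its action
    label. These are the triangle plots used to visualise boundary collapse
    and magnitude sensitivity.
    """

    v: float
    t: float
    table: pd.DataFrame  # columns: u, w, v, t, action

    @property
    def n_points(self) -> int:
        return len(self.table)

    def wait_fraction(self) -> float:
        if self.n_points == 0:
            return 0.0
        return float((self.table["action"] == "wait").mean())

    def wait_area(self) -> int:
        """Number of grid points in the slice labelled wait."""
        return int((self.table["action"] == "wait").sum())


def project_boundary_slice(p: PolicyGrid, t: float, v: float) -> BoundarySlice:
    """Project the action labels at time ``t`` onto the plane of common value ``v``."""
    cfg = p.config
    if cfg.n_options != 3:
        raise ConfigError("boundary projection is defined for 3 options")
    if not (cfg.grid_lo <= v <= cfg.grid_hi):
        raise ValueError(f"plane v={v} lies outside the grid support [{cfg.grid_lo}, {cfg.grid_hi}]")
    k = p.slice_index(t)
    grid = estimate_grid(cfg)
    h = grid[1] - grid[0]
    X1, X2, X3 = np.meshgrid(grid, grid, grid, indexing="ij")
    total = X1 + X2 + X3
    # perpendicular distance to the plane is |sum - 3v| / sqrt(3)
    mask = np.abs(total - 3.0 * v) <= 0.5 * h * np.sqrt(3.0)
    pts = np.stack([X1[mask], X2[mask], X3[mask]], axis=1)
    acts = p.actions[k][mask]
    table = pd.DataFrame(
        {
            "u": pts @ _U_BASIS,
            "w": pts @ _W_BASIS,
            "v": v,
            "t": p.times[k],
            "action": [_ACTION_NAMES[int(a)] for a in acts],
        }
    )
    return BoundarySlice(v=v, t=float(p.times[k]), table=table)
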