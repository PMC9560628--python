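"""Stochastic simulation of Bayes-optimal agents applying a solved policy.

Each trial accumulates one momentary evidence sample per option per step of
length ``sim_dt`` (default 5e-3, much finer than the DP slice spacing),
updates the posterior-mean estimates in closed form, and consults the policy:
the stop/continue decision is taken by trilinear interpolation of the signed
margin (continuation minus stop value) at the nearest policy time slice,
which avoids the grid aliasing a nearest-node action lookup would produce at
sim_dt << δt. On stopping, the chosen option is the argmax of the posterior
means, ties broken uniformly at random. Trials that reach the horizon are
resolved by forced choice and flagged censored; censored trials are kept in
the mean RT (conservative) and the censoring fraction is always reported.

Randomness is organised as one independent stream per option (derived from
the batch seed and an option key), plus a separate tie-breaking stream, so
that permuting the true values together with the option keys permutes
choices and leaves reaction times bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .policy import BellmanConfig, PolicyGrid, solve_policy

__all__ = [
    "TrialResult",
    "RTSummary",
    "SweepResult",
    "SlopeEstimate",
    "simulate_trial",
    "simulate_batch",
    "simulate_trials_table",
    "magnitude_sweep",
    "magnitude_slope",
]

logger = logging.getLogger(__name__)

_TIE_STREAM_KEY = 0x7FF1  # reserved sub-stream key for tie-breaking draws


@dataclass(frozen=True)
class TrialResult:
    """One simulated decision."""

    rt: float
    choice: int
    censored: bool
    trajectory_len: int


@dataclass(frozen=True)
class RTSummary:
    """Aggregates of a batch of simulated trials."""

    n: int
    mean_rt: float
    ci95: tuple[float, float]
    choice_freq: np.ndarray
    censored_frac: float


def _run_batch(
    p: PolicyGrid,
    true_values,
    n: int,
    sim_dt: float,
    seed: int,
    option_keys=None,
):
    """Vectorized core: returns (rt, choice, censored, trajectory_len) arrays."""
    cfg = p.config
    k = cfg.n_options
    true_values = np.asarray(true_values, dtype=float)
    if true_values.shape != (k,):
        raise ValueError(f"expected {k} true values, got shape {true_values.shape}")
    if sim_dt <= 0:
        raise ValueError("sim_dt must be positive")
    if n < 1:
        raise ValueError("trial count must be at least 1")
    if option_keys is None:
        option_keys = tuple(range(k))

    gens = [np.random.default_rng([int(seed), int(key)]) for key in option_keys]
    tie_rng = np.random.default_rng([int(seed), _TIE_STREAM_KEY])

    n_steps = int(round(cfg.horizon / sim_dt))
    ev_sd = np.sqrt(cfg.obs_var * sim_dt)

    sum_x = np.zeros((n, k))
    rt = np.full(n, cfg.horizon)
    choice = np.full(n, -1, dtype=np.int64)
    censored = np.zeros(n, dtype=bool)
    traj_len = np.full(n, n_steps, dtype=np.int64)
    active = np.arange(n)

    interp_cache: dict[int, object] = {}
    n_clamped = 0

    for step in range(n_steps + 1):
        if active.size == 0:
            break
        t = step * sim_dt
        post = (cfg.prior_mean * cfg.obs_var + cfg.prior_var * sum_x[active]) / (
            cfg.obs_var + cfg.prior_var * t
        )

        if step == n_steps:
            stopped = np.ones(active.size, dtype=bool)
            censored[active] = True
        else:
            clipped = np.clip(post, cfg.grid_lo, cfg.grid_hi)
            n_clamped += int(np.any(clipped != post, axis=1).sum())
            idx = p.nearest_slice(t)
            itp = interp_cache.get(idx)
            if itp is None:
                itp = interp_cache[idx] = p.margin_interpolator(idx)
            stopped = itp(clipped) <= 0.0

        if np.any(stopped):
            done = active[stopped]
            rt[done] = t
            traj_len[done] = step
            pd_ = post[stopped]
            max_v = pd_.max(axis=1, keepdims=True)
            ties = pd_ == max_v
            n_ties = ties.sum(axis=1)
            # pick the j-th tied option uniformly; first True of cumsum == j
            j = np.floor(tie_rng.random(done.size) * n_ties).astype(np.int64) + 1
            choice[done] = np.argmax(ties.cumsum(axis=1) == j[:, None], axis=1)
            active = active[~stopped]
            if active.size == 0:
                break

        m = active.size
        for i in range(k):
            sum_x[active, i] += gens[i].normal(true_values[i] * sim_dt, ev_sd, size=m)

    if n_clamped:
        logger.info("clamped %d estimate lookups to the grid edge", n_clamped)
    return rt, choice, censored, traj_len


def simulate_trial(p: PolicyGrid, true_values, sim_dt: float = 5e-3, seed: int = 0) -> TrialResult:
    """Simulate a single decision trial against a solved policy."""
    rt, choice, censored, traj = _run_batch(p, true_values, 1, sim_dt, seed)
    return TrialResult(
        rt=float(rt[0]), choice=int(choice[0]), censored=bool(censored[0]), trajectory_len=int(traj[0])
    )


def _summarize(rt, choice, censored, k: int) -> RTSummary:
    n = rt.size
    mean = float(rt.mean())
    se = float(rt.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    freq = np.bincount(choice, minlength=k).astype(float) / n
    return RTSummary(
        n=n,
        mean_rt=mean,
        ci95=(mean - 1.96 * se, mean + 1.96 * se),
        choice_freq=freq,
        censored_frac=float(censored.mean()),
    )


def simulate_batch(
    p: PolicyGrid,
    true_values,
    n: int,
    sim_dt: float = 5e-3,
    seed: int = 0,
    option_keys=None,
) -> RTSummary:
    """Simulate ``n`` independent trials and aggregate them.

    Deterministic given (policy, true values, n, sim_dt, seed).
    """
    rt, choice, censored, _ = _run_batch(p, true_values, n, sim_dt, seed, option_keys)
    return _summarize(rt, choice, censored, p.config.n_options)


def simulate_trials_table(
    p: PolicyGrid, true_values, n: int, sim_dt: float = 5e-3, seed: int = 0
) -> pd.DataFrame:
    """Per-trial records as a DataFrame (columns: trial, rt, choice, censored)."""
    rt, choice, censored, _ = _run_batch(p, true_values, n, sim_dt, seed)
    return pd.DataFrame(
        {"trial": np.arange(n), "rt": rt, "choice": choice, "censored": censored}
    )


@dataclass
class SweepResult:
    """Policy plus the mean-RT curve across equal-value option sets."""

    policy: PolicyGrid
    curve: pd.DataFrame  # columns: v, n, mean_rt, ci_lo, ci_hi, censored_frac


_CURVE_COLUMNS = ["v", "n", "mean_rt", "ci_lo", "ci_hi", "censored_frac"]


def magnitude_sweep(
    cfg: BellmanConfig,
    values,
    n_per_v: int,
    sim_dt: float = 5e-3,
    seed: int = 0,
    policy: PolicyGrid | None = None,
) -> SweepResult:
    """Mean reaction time across equal-value option sets (v, v, v).

    One policy is solved for ``cfg`` and applied to every value; each value
    gets its own derived seed. ``n_per_v = 0`` is a dry run returning the
    policy and an empty curve.
    """
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(values) < 0):
        raise ValueError("sweep values must be sorted ascending")
    if policy is None:
        policy = solve_policy(cfg)
    if n_per_v == 0:
        return SweepResult(policy=policy, curve=pd.DataFrame(columns=_CURVE_COLUMNS))

    sub_seeds = np.random.SeedSequence(int(seed)).generate_state(values.size) % (2**31)
    rows = []
    for v, s in zip(values, sub_seeds):
        summ = simulate_batch(policy, np.full(cfg.n_options, v), n_per_v, sim_dt, int(s))
        rows.append(
            {
                "v": v,
                "n": summ.n,
                "mean_rt": summ.mean_rt,
                "ci_lo": summ.ci95[0],
                "ci_hi": summ.ci95[1],
                "censored_frac": summ.censored_frac,
            }
        )
        logger.info("v=%g: mean RT %.4f (censored %.1f%%)", v, summ.mean_rt, 100 * summ.censored_frac)
    return SweepResult(policy=policy, curve=pd.DataFrame(rows, columns=_CURVE_COLUMNS))


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope of mean RT against the common value v, with its pooled SE."""

    slope: float
    se: float

    def __float__(self) -> float:
        return self.slope

    def excludes_zero(self) -> bool:
        """Whether the 95% interval slope ± 1.96 SE excludes zero."""
        return abs(self.slope) > 1.96 * self.se


def magnitude_slope(curve: pd.DataFrame) -> SlopeEstimate:
    """Scalar index of magnitude sensitivity: OLS slope of mean RT on v.

    The standard error pools the per-point Monte-Carlo uncertainty from the
    curve's confidence intervals when present, otherwise falls back to the
    OLS residual estimate.
    """
    if len(curve) < 2:
        raise ValueError("need at least 2 sweep points for a slope")
    v = curve["v"].to_numpy(dtype=float)
    y = curve["mean_rt"].to_numpy(dtype=float)
    vc = v - v.mean()
    sxx = float(np.sum(vc**2))
    if sxx == 0.0:
        raise ValueError("sweep values are all identical")
    w = vc / sxx
    slope = float(np.sum(w * (y - y.mean())))
    if {"ci_lo", "ci_hi"}.issubset(curve.columns) and curve["ci_hi"].notna().all():
        se_pts = (curve["ci_hi"].to_numpy() - curve["ci_lo"].to_numpy()) / (2 * 1.96)
        se = float(np.sqrt(np.sum((w * se_pts) ** 2)))
    else:
        resid = (y - y.mean()) - slope * vc
        dof = max(len(curve) - 2, 1)
        se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return SlopeEstimate(slope=slope, se=se)
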