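"""Run configuration: JSON schema, validation, defaults, round-tripping.

A run config is a plain JSON object. Minimal example::

    {"regime": "geometric", "gamma": 0.1}

Defaults fill in the standard parameterisation (Gaussian prior
Normal(1.5, 5), observation noise variance 2, logistic-or-linear utility,
simulation step 5e-3). Unknown keys anywhere in the document are rejected,
and every run writes its fully-resolved config beside its outputs so that
results are reproducible from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .policy import BellmanConfig
from .utility import UtilityFunction

__all__ = ["RunConfig", "load_config", "bellman_to_dict", "bellman_from_dict", "config_digest"]

_UTILITY_KEYS = {"family", "m", "s"}
_BELIEF_KEYS = {"prior_mean", "prior_var", "obs_var"}
_GRID_KEYS = {"lo", "hi", "n"}
_TOP_KEYS = {
    "regime",
    "gamma",
    "c",
    "rho",
    "t_w",
    "utility",
    "belief",
    "grid",
    "dt",
    "horizon",
    "n_options",
    "reward_mode",
    "sim_dt",
    "n_trials",
    "seed",
}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(d) - allowed)
    if unknown:
        raise ConfigError(f"unknown {where} keys: {', '.join(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved run configuration (solver + simulation settings)."""

    regime: str
    gamma: float | None = None
    c: float = 0.0
    rho: float | None = None
    t_w: float = 1.0
    utility: UtilityFunction = field(default_factory=UtilityFunction)
    prior_mean: float = 1.5
    prior_var: float = 5.0
    obs_var: float = 2.0
    grid_lo: float = -5.0
    grid_hi: float = 5.0
    grid_n: int = 41
    dt: float = 0.05
    horizon: float = 3.0
    n_options: int = 3
    reward_mode: str = "expected"
    sim_dt: float = 5e-3
    n_trials: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        self.to_bellman()  # delegates solver-parameter validation

    def to_bellman(self) -> BellmanConfig:
        try:
            return BellmanConfig(
                cost_regime=self.regime,
                utility=self.utility,
                n_options=self.n_options,
                prior_mean=self.prior_mean,
                prior_var=self.prior_var,
                obs_var=self.obs_var,
                c=self.c,
                rho=self.rho,
                t_w=self.t_w,
                gamma=self.gamma,
                dt=self.dt,
                horizon=self.horizon,
                grid_lo=self.grid_lo,
                grid_hi=self.grid_hi,
                grid_n=self.grid_n,
                reward_mode=self.reward_mode,
            )
        except ValueError as e:
            raise ConfigError(str(e)) from e

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, _TOP_KEYS, "config")
        kwargs: dict = {}
        if "regime" not in d:
            raise ConfigError("config requires a 'regime' key (linear | geometric)")
        kwargs["regime"] = d["regime"]
        for key in ("gamma", "c", "rho", "t_w", "dt", "horizon", "n_options",
                    "reward_mode", "sim_dt", "n_trials", "seed"):
            if key in d:
                kwargs[key] = d[key]
        if "utility" in d:
            u = d["utility"]
            _check_keys(u, _UTILITY_KEYS, "utility")
            try:
                kwargs["utility"] = UtilityFunction(
                    family=u.get("family", "linear"), m=u.get("m"), s=u.get("s")
                )
            except ValueError as e:
                raise ConfigError(str(e)) from e
        if "belief" in d:
            b = d["belief"]
            _check_keys(b, _BELIEF_KEYS, "belief")
            for src, dst in (("prior_mean", "prior_mean"), ("prior_var", "prior_var"), ("obs_var", "obs_var")):
                if src in b:
                    kwargs[dst] = b[src]
        if "grid" in d:
            g = d["grid"]
            _check_keys(g, _GRID_KEYS, "grid")
            for src, dst in (("lo", "grid_lo"), ("hi", "grid_hi"), ("n", "grid_n")):
                if src in g:
                    kwargs[dst] = g[src]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        u: dict = {"family": self.utility.family}
        if self.utility.family == "logistic":
            u.update(m=self.utility.m, s=self.utility.s)
        return {
            "regime": self.regime,
            "gamma": self.gamma,
            "c": self.c,
            "rho": self.rho,
            "t_w": self.t_w,
            "utility": u,
            "belief": {
                "prior_mean": self.prior_mean,
                "prior_var": self.prior_var,
                "obs_var": self.obs_var,
            },
            "grid": {"lo": self.grid_lo, "hi": self.grid_hi, "n": self.grid_n},
            "dt": self.dt,
            "horizon": self.horizon,
            "n_options": self.n_options,
            "reward_mode": self.reward_mode,
            "sim_dt": self.sim_dt,
            "n_trials": self.n_trials,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def load_config(path) -> RunConfig:
    """Load and validate a JSON run config, applying defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        d = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ConfigError(f"invalid JSON in {path}: {e}") from e
    if not isinstance(d, dict):
        raise ConfigError("config must be a JSON object")
    return RunConfig.from_dict(d)


# --------------------------------------------------------------------------
# BellmanConfig <-> dict (for embedding in policy containers)


def bellman_to_dict(cfg: BellmanConfig) -> dict:
    d = dataclasses.asdict(cfg)
    u = d.pop("utility")
    if not isinstance(u, dict):  # duck-typed utility objects
        u = {"family": getattr(u, "family", "custom"), "m": getattr(u, "m", None), "s": getattr(u, "s", None)}
    if u.get("family") == "linear":
        u = {"family": "linear", "m": None, "s": None}
    d["utility"] = u
    return d


def bellman_from_dict(d: dict) -> BellmanConfig:
    d = dict(d)
    u = d.pop("utility")
    utility = UtilityFunction(family=u["family"], m=u.get("m"), s=u.get("s"))
    return BellmanConfig(utility=utility, **d)


def config_digest(d: dict) -> str:
    """Stable content hash of a config dict (canonical JSON, sha256)."""
    blob = json.dumps(d, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()
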