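"""Subjective utility functions.

Maps raw option values to subjective rewards. Two families are supported:
the identity (linear utility, ``r = x``) and a logistic sigmoid

    U(x) = m * (2 / (1 + exp(-s*x)) - 1) = m * tanh(s*x / 2),

which spans near-linear shapes (small ``s``, where ``U(x) ~ (m*s/2) x``)
through to near-stepwise shapes (large ``s``, where ``U(x) -> m*sign(x)``).
``m`` sets the utility half-range (output lies strictly in (-m, m)) and
``s`` the steepness at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["UtilityFunction", "linear_utility", "logistic_utility", "shape_profile"]

# nodes/weights for Gauss-Hermite expectation under a Gaussian posterior
_GH_DEGREE = 41


@dataclass(frozen=True)
class UtilityFunction:
    """Subjective utility, either the identity or a logistic sigmoid.

    Parameters
    ----------
    family:
        ``"linear"`` (identity; ``m`` and ``s`` are ignored and must be None)
        or ``"logistic"``.
    m:
        Utility half-range of the logistic family, same units as value.
        Must be positive.
    s:
        Logistic slope parameter, per value unit. Must be strictly positive;
        ``s = 0`` is rejected rather than treated as linear.
    """

    family: str = "linear"
    m: float | None = None
    s: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown utility family {self.family!r}")
        if self.family == "logistic":
            if self.m is None or self.s is None:
                raise ValueError("logistic utility requires m and s")
            if not (np.isfinite(self.m) and self.m > 0):
                raise ValueError(f"logistic half-range m must be positive, got {self.m}")
            if not (np.isfinite(self.s) and self.s > 0):
                raise ValueError(f"logistic slope s must be strictly positive, got {self.s}")
        elif self.m is not None or self.s is not None:
            raise ValueError("linear utility takes no shape parameters")

    def evaluate(self, x):
        """Utility of raw value ``x`` (scalar or array, vectorized elementwise)."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("utility input must be finite")
        if self.family == "linear":
            out = x.copy()
        else:
            # m * (2/(1+e^{-sx}) - 1) == m * tanh(sx/2), numerically stable
            out = self.m * np.tanh(0.5 * self.s * x)
        return float(out) if out.ndim == 0 else out

    __call__ = evaluate

    def expected(self, mean, var):
        """E[U(X)] for X ~ Normal(mean, var), via Gauss-Hermite quadrature.

        Used by the optional ``reward_mode="expected"`` of the dynamic
        program; for the linear family this is exactly the mean.
        """
        mean = np.asarray(mean, dtype=float)
        var = float(var)
        if var < 0:
            raise ValueError("variance must be nonnegative")
        if self.family == "linear" or var == 0.0:
            return self.evaluate(mean)
        nodes, weights = np.polynomial.hermite_e.hermegauss(_GH_DEGREE)
        sd = np.sqrt(var)
        vals = self.evaluate(mean[..., None] + sd * nodes)
        out = vals @ (weights / np.sqrt(2.0 * np.pi))
        return float(out) if out.ndim == 0 else out


def linear_utility() -> UtilityFunction:
    return UtilityFunction(family="linear")


def logistic_utility(m: float, s: float) -> UtilityFunction:
    return UtilityFunction(family="logistic", m=m, s=s)


def shape_profile(u: UtilityFunction, xs) -> pd.DataFrame:
    """Tabulate ``U(x)`` over a sorted value grid.

    Returns a DataFrame with columns ``x`` and ``utility``; output is
    monotone nondecreasing for any valid utility. Useful for rendering
    utility-shape diagnostics.
    """
    xs = np.asarray(xs, dtype=float)
    if xs.size == 0:
        raise ValueError("value grid must be nonempty")
    if np.any(np.diff(xs) < 0):
        raise ValueError("value grid must be sorted ascending")
    return pd.DataFrame({"x": xs, "utility": u.evaluate(xs)})
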