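"""Gaussian conjugate belief over option values.

Each option's true value rate ``x̄`` is unknown; the decision-maker holds a
Gaussian prior Normal(x̄_p, σ_p²) and accumulates momentary evidence samples

    x_τ ~ Normal(x̄ dt, σ_a² dt)

independently per option and time step. Because the likelihood of the running
sum Σx_τ after elapsed time t is Normal(x̄ t, σ_a² t), the posterior over x̄
stays Gaussian with

    mean      (x̄_p σ_a² + σ_p² Σx) / (σ_a² + σ_p² t)
    variance  1 / (1/σ_p² + t/σ_a²)

and the sequence of posterior means is a martingale: conditional on the
current belief, the posterior mean a step δt later is Normal(current mean,
s²) with s² the drop in posterior variance over the step. That one-step law
is what the dynamic program integrates over.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["GaussianBelief", "sample_evidence", "posterior_mean", "posterior_var", "transition_std"]


@dataclass(frozen=True)
class GaussianBelief:
    """Belief state of one option: prior, noise level, and sufficient statistics.

    ``cum_evidence`` is the running sum of momentary evidence samples; together
    with elapsed time ``t`` it is sufficient for the posterior.
    """

    prior_mean: float
    prior_var: float
    obs_var: float
    t: float = 0.0
    cum_evidence: float = 0.0

    def __post_init__(self) -> None:
        if self.prior_var <= 0:
            raise ValueError("prior variance must be positive")
        if self.obs_var <= 0:
            raise ValueError("observation noise variance must be positive")
        if self.t < 0:
            raise ValueError("elapsed time must be nonnegative")

    def posterior_mean(self) -> float:
        num = self.prior_mean * self.obs_var + self.prior_var * self.cum_evidence
        den = self.obs_var + self.prior_var * self.t
        return num / den

    def posterior_var(self, t: float | None = None) -> float:
        t = self.t if t is None else t
        return 1.0 / (1.0 / self.prior_var + t / self.obs_var)

    def transition_std(self, dt: float) -> float:
        """SD of the posterior-mean increment over the next ``dt`` of evidence."""
        if dt <= 0:
            raise ValueError("time step must be positive")
        drop = self.posterior_var(self.t) - self.posterior_var(self.t + dt)
        return float(np.sqrt(max(drop, 0.0)))

    def updated(self, evidence: float, dt: float) -> "GaussianBelief":
        """Belief after absorbing one momentary evidence sample of length ``dt``."""
        if dt <= 0:
            raise ValueError("time step must be positive")
        return replace(self, t=self.t + dt, cum_evidence=self.cum_evidence + evidence)


def sample_evidence(true_values, obs_var: float, dt: float, rng: np.random.Generator):
    """Draw one momentary evidence sample per option.

    Each component is Normal(x̄_i dt, σ_a² dt), independent across options.
    ``obs_var = 0`` is the noise-free limiting mode and returns ``x̄ dt``.
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    if obs_var < 0:
        raise ValueError("observation noise variance must be nonnegative")
    true_values = np.asarray(true_values, dtype=float)
    if obs_var == 0.0:
        return true_values * dt
    return rng.normal(true_values * dt, np.sqrt(obs_var * dt))


# Functional aliases mirroring the method surface.

def posterior_mean(b: GaussianBelief) -> float:
    return b.posterior_mean()


def posterior_var(b: GaussianBelief) -> float:
    return b.posterior_var()


def transition_std(b: GaussianBelief, dt: float) -> float:
    return b.transition_std(dt)
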