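"""Synthetic experimental designs and reaction-time data generators.

Reproduces the structure of two behavioural designs used to probe magnitude
sensitivity: (i) a ternary brightness-discrimination schedule — every
ordered triple over a set of brightness levels, equal triples repeated more
often than unequal ones, with per-frame Gaussian luminance noise whose SD is
proportional to the mean brightness (constant signal-to-noise ratio); and
(ii) a balanced slime-mould foraging design crossing food-quality
concentrations with replicates. A parametric RT generator produces
subject-level datasets with a linear mean-RT-vs-magnitude trend for
end-to-end pipeline tests.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

__all__ = [
    "generate_trial_schedule",
    "frame_noise",
    "slime_design",
    "equal_trials_design",
    "generate_synthetic_rt_dataset",
]

ITI_CHOICES = (0.5, 1.0, 1.5)  # inter-trial intervals, seconds
FRAME_NOISE_CV = 0.25  # luminance noise SD as a fraction of mean brightness

# shape of the lognormal RT residual before standardisation; 0.5 gives the
# moderate right skew typical of empirical reaction times
_RT_RESIDUAL_SIGMA = 0.5


def generate_trial_schedule(
    levels,
    equal_repeats: int,
    unequal_repeats: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pseudo-randomised schedule over all ordered brightness triples.

    Equal triples (all three patches at the same level) appear
    ``equal_repeats`` times each, every other ordered triple
    ``unequal_repeats`` times; row order is shuffled by ``rng`` and each
    trial gets an inter-trial interval drawn uniformly from
    {0.5, 1.0, 1.5} s. With 4 levels and repeats (10, 1) this yields the
    canonical 100-trial session (40 equal + 60 unequal rows out of the
    4^3 = 64 ordered combinations).
    """
    levels = sorted(set(float(x) for x in np.atleast_1d(levels)))
    if not levels:
        raise ValueError("brightness level set must be nonempty")
    if equal_repeats < 0 or unequal_repeats < 0:
        raise ValueError("repeat counts must be nonnegative")

    rows = []
    for triple in itertools.product(levels, repeat=3):
        is_equal = triple[0] == triple[1] == triple[2]
        reps = equal_repeats if is_equal else unequal_repeats
        rows.extend((triple, is_equal) for _ in range(reps))

    order = rng.permutation(len(rows))
    records = []
    for trial, j in enumerate(order):
        (b1, b2, b3), is_equal = rows[j]
        records.append(
            {
                "trial": trial,
                "b1": b1,
                "b2": b2,
                "b3": b3,
                "is_equal": is_equal,
                "iti": float(rng.choice(ITI_CHOICES)),
            }
        )
    return pd.DataFrame(records, columns=["trial", "b1", "b2", "b3", "is_equal", "iti"])


def frame_noise(mean_brightness, rng: np.random.Generator, clip: bool = False):
    """One noisy luminance frame: mean + Normal(0, (0.25 * mean)^2).

    The noise SD scales with the mean, keeping the signal-to-noise ratio
    constant across magnitudes. Values are NOT clipped to [0, 1] unless
    ``clip=True``, since clipping would break that constant-SNR property.
    Vectorizes over arrays of means.
    """
    mean_brightness = np.asarray(mean_brightness, dtype=float)
    if np.any(mean_brightness < 0):
        raise ValueError("mean brightness must be nonnegative")
    out = np.asarray(rng.normal(mean_brightness, FRAME_NOISE_CV * mean_brightness))
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def slime_design(concentrations, replicates: int) -> pd.DataFrame:
    """Balanced foraging design: every concentration × every replicate.

    Columns: ``replicate`` (unique id), ``concentration`` (g/L of egg yolk
    in the food source). Four concentrations at 50 replicates give the
    canonical 200-row design.
    """
    concentrations = sorted(set(float(c) for c in np.atleast_1d(concentrations)))
    if not concentrations:
        raise ValueError("concentration set must be nonempty")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rows = [
        {"replicate": i * replicates + r, "concentration": c}
        for i, c in enumerate(concentrations)
        for r in range(replicates)
    ]
    return pd.DataFrame(rows, columns=["replicate", "concentration"])


def equal_trials_design(n_subjects: int, magnitudes, repeats: int) -> pd.DataFrame:
    """Long-format (subject, magnitude) design of equal-alternative trials."""
    if n_subjects < 1 or repeats < 1:
        raise ValueError("need at least one subject and one repeat")
    magnitudes = [float(m) for m in np.atleast_1d(magnitudes)]
    rows = [
        {"subject": s, "magnitude": m}
        for s in range(n_subjects)
        for m in magnitudes
        for _ in range(repeats)
    ]
    return pd.DataFrame(rows, columns=["subject", "magnitude"])


def generate_synthetic_rt_dataset(
    design: pd.DataFrame,
    slope: float,
    intercept: float,
    subject_sd: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Synthetic reaction times with a linear magnitude trend.

    rt = intercept + slope * magnitude + subject random intercept
    (Normal(0, subject_sd^2)) + a lognormal residual standardised to SD
    ``noise_sd`` (right-skewed, as empirical RTs are). ``design`` must carry
    ``subject`` and ``magnitude`` columns; the result adds an ``rt`` column.

    This is a synthetic stand-in for unavailable raw behavioural data,
    intended for parameter-recovery and pipeline tests only.
    """
    if subject_sd < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    for col in ("subject", "magnitude"):
        if col not in design.columns:
            raise ValueError(f"design is missing required column {col!r}")

    subjects = design["subject"].to_numpy()
    uniq = pd.unique(subjects)
    offsets = dict(zip(uniq, rng.normal(0.0, subject_sd, size=uniq.size)))

    sig = _RT_RESIDUAL_SIGMA
    raw = rng.lognormal(0.0, sig, size=len(design))
    ln_mean = np.exp(sig**2 / 2)
    ln_sd = np.sqrt((np.exp(sig**2) - 1.0) * np.exp(sig**2))
    resid = (raw - ln_mean) / ln_sd * noise_sd

    out = design.copy()
    out["rt"] = (
        intercept
        + slope * design["magnitude"].to_numpy(dtype=float)
        + np.array([offsets[s] for s in subjects])
        + resid
    )
    return out
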