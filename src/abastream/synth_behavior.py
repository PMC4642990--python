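"""Seeded generator of synthetic behavioral cohorts.

Emulates the statistical structure the behavioral pipeline assumes: a
cohort of subjects with widely spread individual switching rates, per-trial
alternating integrated/segregated percept durations that are log-normally
distributed, an X-shaped dependence of the two percepts' mean durations on
the tone frequency difference crossing at a configurable equidominance
point, and inflated first durations whose inflation decays with Δf.

What it deliberately does not emulate: key-press mechanics (both/neither
key intervals, reaction-time lags), within-session drift, or any departure
from strict percept alternation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import DIALECT_COLUMNS, EXPERIMENT_DF_VALUES

__all__ = ["EffectSpec", "generate_cohort"]


@dataclass(frozen=True)
class EffectSpec:
    """Tunable structure of a synthetic cohort.

    * ``crossover_df`` — equidominance point (semitones): integrated and
      segregated mean durations are equal there.
    * ``branch_slope`` — log-log slope b of the X diagram: the integrated
      mean scales as (df/df0)^-b and the segregated mean as (df/df0)^+b.
      Both percepts' means away from equidominance then sum to more than
      twice the equidominance mean, so the generated cohorts satisfy the
      generalized Levelt II property (the measure η = cosh(b ln(df/df0)),
      minus 1, is positive away from the crossover).
    * ``duration_cv`` — coefficient of variation of individual percept
      durations (log-normal within each subject x condition x percept).
    * ``tglob_range`` — the span (seconds) of subject grand mean durations;
      subjects are drawn log-uniformly across it.
    * ``first_factor`` / ``first_decay`` — the first duration's mean is
      multiplied by 1 + first_factor * exp(-(df - 1) / first_decay); the
      inflation is largest at small Δf.
    """

    crossover_df: float = 5.0
    branch_slope: float = 0.5
    duration_cv: float = 0.83
    tglob_range: tuple = (2.6, 14.8)
    first_factor: float = 1.5
    first_decay: float = 5.0

    def __post_init__(self):
        lo, hi = self.tglob_range
        if not (0 < lo <= hi):
            raise ValueError("tglob_range must be positive and ordered")
        if self.duration_cv <= 0:
            raise ValueError("duration_cv must be positive")
        if self.crossover_df <= 0:
            raise ValueError("crossover_df must be positive")
        if self.first_factor < 0 or self.first_decay <= 0:
            raise ValueError("first-duration inflation must be nonnegative")

    def mean_multiplier(self, delta_f: float, percept: str) -> float:
        x = np.log(delta_f / self.crossover_df)
        sign = -1.0 if percept == "integrated" else 1.0
        return float(np.exp(sign * self.branch_slope * x))

    def first_multiplier(self, delta_f: float) -> float:
        return 1.0 + self.first_factor * float(
            np.exp(-(delta_f - 1.0) / self.first_decay))


def _lognormal_draw(rng, mean: float, cv: float, size=None):
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def generate_cohort(n_subjects: int = 15, reps: int = 3,
                    df_values=EXPERIMENT_DF_VALUES,
                    trial_duration: float = 240.0,
                    effect: EffectSpec | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Generate a cohort as a tidy per-duration table (canonical dialect).

    Within a trial, percept types alternate strictly starting from a
    random first percept; the final duration is truncated at the trial end
    and marked incomplete.  A fixed seed reproduces the cohort exactly.
    """
    if n_subjects < 1 or reps < 1:
        raise ValueError("need at least one subject and one repetition")
    if trial_duration <= 0:
        raise ValueError("trial_duration must be positive")
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)
    lo, hi = effect.tglob_range
    tglob_latent = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_subjects))

    rows = []
    for si in range(n_subjects):
        subject = f"S{si + 1:02d}"
        base = tglob_latent[si]
        for rep in range(1, reps + 1):
            for df in df_values:
                percept_is_int = bool(rng.integers(2))
                t = 0.0
                first = True
                while t < trial_duration:
                    percept = "integrated" if percept_is_int else "segregated"
                    mean = base * effect.mean_multiplier(df, percept)
                    if first:
                        mean *= effect.first_multiplier(df)
                    dur = float(_lognormal_draw(rng, mean, effect.duration_cv))
                    incomplete = t + dur >= trial_duration
                    if incomplete:
                        dur = trial_duration - t
                    rows.append({
                        "subject": subject, "repetition": rep,
                        "delta_f": float(df), "onset_s": t,
                        "duration_s": dur, "percept": percept,
                        "is_first": first, "is_incomplete": incomplete,
                    })
                    t += dur
                    first = False
                    percept_is_int = not percept_is_int
    return pd.DataFrame(rows, columns=list(DIALECT_COLUMNS))
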