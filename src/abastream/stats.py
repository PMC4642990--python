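"""Dominance-duration statistics: normalization, CV, distribution fits, KS tests.

Dominance durations of bistable perception are conventionally compared with
gamma and log-normal distributions after normalizing each percept type's
durations by its mean.  The coefficient of variation (sample SD over mean)
indexes where the alternations sit between adaptation-driven (low CV) and
noise-driven (high CV) switching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "DurationSample", "duration_summary", "normalize_by_percept_mean",
    "fit_gamma", "fit_lognormal", "ks_one_sample", "ks_two_sample",
    "FitResult",
]


@dataclass
class DurationSample:
    """A sample of dominance durations with provenance metadata.

    ``normalization`` records the constant(s) the values were divided by
    (one per percept type when pooled across types), or ``None`` for raw
    seconds.
    """

    values: np.ndarray
    provenance: str = "model"            # model | experiment | synthetic
    normalization: dict | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size and (not np.all(np.isfinite(v)) or np.any(v <= 0)):
            raise ValueError("durations must be finite and positive")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.size


def duration_summary(sample) -> dict:
    """Mean, sample SD (n-1 denominator) and CV = SD / mean."""
    v = _values(sample)
    if v.size == 0:
        raise ValueError("empty duration sample")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return {"n": int(v.size), "mean": mean, "sd": sd, "cv": sd / mean}


def normalize_by_percept_mean(durations: pd.DataFrame) -> DurationSample:
    """Pool durations across percept types after dividing by each type's mean.

    ``durations`` carries columns ``duration_s`` and ``percept`` (as produced
    by :func:`abastream.decode.extract_durations`).
    """
    consts = {}
    parts = []
    for name, grp in durations.groupby("percept"):
        m = grp["duration_s"].mean()
        consts[name] = float(m)
        parts.append(grp["duration_s"].to_numpy() / m)
    values = np.concatenate(parts) if parts else np.array([])
    return DurationSample(values=values, normalization=consts)


@dataclass
class FitResult:
    """Parameters and goodness of a distribution fit plus its KS test."""

    distribution: str
    params: dict
    log_likelihood: float
    n: int
    ks_d: float | None = None
    ks_p: float | None = None
    frozen: object = field(default=None, repr=False)

    def to_json(self) -> str:
        d = {"distribution": self.distribution, **self.params,
             "log_likelihood": self.log_likelihood, "n": self.n,
             "D": self.ks_d, "p": self.ks_p}
        return json.dumps(d)


def fit_gamma(sample) -> FitResult:
    """Maximum-likelihood fit of the two-parameter gamma (shape k, scale θ).

    The density is x^(k-1) e^(-x/θ) / (Γ(k) θ^k) with mean kθ; location is
    fixed at zero.
    """
    v = _values(sample)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("gamma fit requires a nonempty positive sample")
    k, _, theta = _sps.gamma.fit(v, floc=0)
    frozen = _sps.gamma(k, loc=0, scale=theta)
    ll = float(frozen.logpdf(v).sum())
    return FitResult("gamma", {"shape": float(k), "scale": float(theta)},
                     ll, int(v.size), frozen=frozen)


def fit_lognormal(sample) -> FitResult:
    """Closed-form MLE of the log-normal: μ, σ are mean and SD of log-values.

    The fitted mean is exp(μ + σ²/2).
    """
    v = _values(sample)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("log-normal fit requires a nonempty positive sample")
    logs = np.log(v)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))          # MLE uses the n-denominator
    frozen = _sps.lognorm(sigma if sigma > 0 else 1e-300, scale=np.exp(mu))
    ll = float(frozen.logpdf(v).sum()) if sigma > 0 else np.inf
    return FitResult("lognormal", {"mu": mu, "sigma": sigma},
                     ll, int(v.size), frozen=frozen)


def ks_one_sample(sample, fitted) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted distribution.

    ``fitted`` is a :class:`FitResult` or any frozen scipy distribution.
    Returns (D, asymptotic p).  D is the sup-distance between the empirical
    step CDF and the fitted CDF.  The p-value treats the fitted parameters
    as fixed (no correction for having estimated them from the same
    sample), replicating the field's customary procedure.
    """
    v = _values(sample)
    if v.size == 0:
        raise ValueError("empty sample")
    frozen = fitted.frozen if isinstance(fitted, FitResult) else fitted
    res = _sps.kstest(v, frozen.cdf, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(sample1, sample2) -> tuple[float, float]:
    """Two-sample KS test (asymptotic p): are both drawn from one distribution?"""
    a, b = _values(sample1), _values(sample2)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = _sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fit_and_test(sample, rng=None, subsample: int | None = None):
    """Gamma and log-normal fits with their one-sample KS tests.

    Optionally subsamples (without replacement, seeded via ``rng``) before
    fitting, as done when very large duration pools are compared against
    percept reports.
    """
    v = _values(sample)
    if subsample is not None and v.size > subsample:
        rng = np.random.default_rng(rng)
        v = rng.choice(v, size=subsample, replace=False)
    out = {}
    for fitter in (fit_gamma, fit_lognormal):
        fr = fitter(v)
        fr.ks_d, fr.ks_p = ks_one_sample(v, fr)
        out[fr.distribution] = fr
    return out


def _values(sample) -> np.ndarray:
    if isinstance(sample, DurationSample):
        return sample.values
    if isinstance(sample, pd.DataFrame):
        return sample["duration_s"].to_numpy(dtype=float)
    return np.asarray(sample, dtype=float)
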