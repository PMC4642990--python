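"""Core model definitions: parameters, state, and the deterministic vector field.

The network consists of three firing-rate units placed on a tonotopic axis:
two peripheral units centred at the best frequencies of the A and B tones and
one central unit centred midway between them.  Each unit ``k`` carries five
dynamic variables: firing rate ``r_k``, spike-frequency adaptation ``a_k``,
slow NMDA-like recurrent excitation ``e_k``, synaptic depression ``d_k``
acting on that excitation, and an additive Ornstein-Uhlenbeck noise ``chi_k``.
Competition arises from mutual inhibition whose strength may decay with
tonotopic distance (local variant) or be distance-independent (global
variant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "NetworkState",
    "StimulusDescriptor",
    "PRESETS",
    "get_preset",
    "firing_rate",
    "input_gain",
    "inhibition_strength",
    "drift",
]

#: order of the 15 dynamic variables in flat-vector representations
STATE_VARS = (
    "r_A", "r_AB", "r_B",
    "a_A", "a_AB", "a_B",
    "e_A", "e_AB", "e_B",
    "d_A", "d_AB", "d_B",
    "chi_A", "chi_AB", "chi_B",
)


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set for the three-unit competition network.

    Time constants are in seconds, tonotopic length scales in semitones and
    all strengths are dimensionless.  Two named presets are provided (see
    :data:`PRESETS`): ``efix_ilcl`` freezes synaptic depression
    (``kappa = 0``) and uses an inhibition footprint that decays with
    tonotopic distance, while ``edyn_igbl`` turns on slow depression of the
    recurrent excitation and makes inhibition global
    (distance-independent, ``sigma_i = inf``).
    """

    # firing-rate sigmoid
    theta_F: float = 0.2
    k_F: float = 12.0
    # input shape
    Lambda2: float = 1.0 / 6.0
    alpha1: float = 0.015
    alpha2: float = 0.0825
    I_p: float = 0.525
    sigma_p: float = 8.0
    # intrinsic strengths
    g: float = 0.065
    gamma: float = 0.075
    beta_i: float = 0.3
    sigma_i: float = 10.0
    beta_e: float = 0.7
    kappa: float = 0.0
    # timescales (seconds)
    tau_r: float = 0.010
    tau_a: float = 1.4
    tau_e: float = 0.070
    tau_X: float = 0.100
    tau_d: float = 3.0
    # input routing: multiplier on w(delta_f) feeding the opposite tone's
    # train to a peripheral unit (0 = peripherals hear their own tone only)
    peripheral_cross_gain: float = 0.0
    # variant flags
    excitation_mode: str = "fixed"   # {"fixed", "dynamic"}
    inhibition_mode: str = "local"   # {"local", "global"}

    def __post_init__(self) -> None:
        for name in ("tau_r", "tau_a", "tau_e", "tau_X", "tau_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be positive")
        if not self.tau_r < self.tau_e < self.tau_a:
            raise ValueError("timescale ordering tau_r < tau_e < tau_a violated")
        if not self.beta_e > self.beta_i:
            raise ValueError("net local excitation requires beta_e > beta_i")
        if self.excitation_mode not in ("fixed", "dynamic"):
            raise ValueError(f"unknown excitation_mode {self.excitation_mode!r}")
        if self.inhibition_mode not in ("local", "global"):
            raise ValueError(f"unknown inhibition_mode {self.inhibition_mode!r}")
        if self.excitation_mode == "fixed" and self.kappa != 0.0:
            raise ValueError("fixed excitation mode requires kappa = 0")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_config(self, path) -> None:
        """Write parameters as a plain-text (YAML key: value) config."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_config(cls, path) -> "ModelParameters":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    def with_updates(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


def _efix_ilcl() -> ModelParameters:
    return ModelParameters()


def _edyn_igbl() -> ModelParameters:
    return ModelParameters(
        I_p=0.47,
        sigma_p=8.5,
        sigma_i=float("inf"),
        beta_e=0.85,
        kappa=0.25,
        tau_d=3.0,
        excitation_mode="dynamic",
        inhibition_mode="global",
    )


PRESETS = {
    "efix_ilcl": _efix_ilcl,
    "edyn_igbl": _edyn_igbl,
}


def get_preset(name: str) -> ModelParameters:
    """Return a named parameter preset (``efix_ilcl`` or ``edyn_igbl``)."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory()


@dataclass
class NetworkState:
    """The 15 dynamic variables of the network at one instant.

    ``r``, ``a`` and ``e`` live in [0, 1] under the dynamics; ``d`` lives in
    (0, 1] and stays pinned at 1 when ``kappa = 0``; the noise variables
    ``chi`` are unbounded.
    """

    r: np.ndarray = field(default_factory=lambda: np.zeros(3))
    a: np.ndarray = field(default_factory=lambda: np.zeros(3))
    e: np.ndarray = field(default_factory=lambda: np.zeros(3))
    d: np.ndarray = field(default_factory=lambda: np.ones(3))
    chi: np.ndarray = field(default_factory=lambda: np.zeros(3))

    #: index of each unit within the length-3 arrays
    UNITS = ("A", "AB", "B")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.r, self.a, self.e, self.d, self.chi])

    @classmethod
    def from_vector(cls, v: Iterable[float]) -> "NetworkState":
        v = np.asarray(v, dtype=float)
        return cls(r=v[0:3].copy(), a=v[3:6].copy(), e=v[6:9].copy(),
                   d=v[9:12].copy(), chi=v[12:15].copy())

    def swapped_AB(self) -> "NetworkState":
        """Return the state with the A and B units exchanged."""
        idx = np.array([2, 1, 0])
        return NetworkState(r=self.r[idx], a=self.a[idx], e=self.e[idx],
                           d=self.d[idx], chi=self.chi[idx])


@dataclass(frozen=True)
class StimulusDescriptor:
    """ABA- triplet stimulus: frequency difference, presentation rate, length.

    The tone duration is tied to the presentation rate, ``TD = 1/PR``, so the
    offset of each tone abuts the onset of the next slot.
    """

    delta_f: float
    pr: float
    duration: float

    def __post_init__(self):
        if self.delta_f <= 0:
            raise ValueError("delta_f must be positive (semitones)")
        if self.pr <= 0:
            raise ValueError("presentation rate must be positive (Hz)")
        if self.duration < 0:
            raise ValueError("duration must be nonnegative (seconds)")

    @property
    def tone_duration(self) -> float:
        return 1.0 / self.pr

    @property
    def triplet_period(self) -> float:
        return 4.0 / self.pr


# ---------------------------------------------------------------------------
# elementary model functions


def firing_rate(u, params: ModelParameters):
    """Sigmoidal rate function ``F(u) = 1 / (1 + exp(k_F (theta_F - u)))``.

    Strictly increasing, bounded in (0, 1), with value 1/2 at the threshold
    ``theta_F`` and maximal slope ``k_F / 4`` there.
    """
    u = np.asarray(u, dtype=float)
    out = 1.0 / (1.0 + np.exp(params.k_F * (params.theta_F - u)))
    return float(out) if out.ndim == 0 else out


def input_gain(delta_f, params: ModelParameters):
    """Tonotopic input spread ``w(df) = I_p exp(-df / sigma_p)``.

    ``delta_f`` is the tonotopic distance (semitones) between the tone and
    the receiving unit; must be nonnegative.
    """
    df = np.asarray(delta_f, dtype=float)
    if np.any(df < 0):
        raise ValueError("delta_f must be nonnegative")
    out = params.I_p * np.exp(-df / params.sigma_p)
    return float(out) if out.ndim == 0 else out


def inhibition_strength(delta_f, params: ModelParameters):
    """Lateral inhibition footprint ``C_i(df)``.

    Gaussian decay ``beta_i exp(-df^2 / (2 sigma_i^2))`` in the local
    variant; the constant ``beta_i`` in the global variant (equivalently
    ``sigma_i -> inf``).
    """
    df = np.asarray(delta_f, dtype=float)
    if params.inhibition_mode == "global" or math.isinf(params.sigma_i):
        out = np.broadcast_to(np.asarray(params.beta_i), df.shape).copy()
    else:
        out = params.beta_i * np.exp(-(df ** 2) / (2.0 * params.sigma_i ** 2))
    return float(out) if out.ndim == 0 else out


def drift(state: NetworkState, inputs, delta_f: float,
          params: ModelParameters) -> NetworkState:
    """Deterministic time-derivative of all 15 variables.

    ``inputs`` is the per-unit drive triple ``(to A, to AB, to B)`` with the
    tonotopic gain factors already applied (see
    :func:`abastream.stimulus.unit_inputs`).  The noise variables enter
    additively inside the sigmoid; their own derivative is reported as the
    deterministic decay ``-chi / tau_X`` (the stochastic innovation is the
    integrator's responsibility).

    Connectivity: the central unit is inhibited by both peripheral units at
    distance ``delta_f / 2``; the peripheral units inhibit each other at
    distance ``delta_f`` and the central unit at ``delta_f / 2``; every unit
    inhibits itself with strength ``C_i(0) = beta_i``.
    """
    iA, iAB, iB = (np.asarray(x, dtype=float) for x in inputs)
    rA, rAB, rB = state.r
    c0 = inhibition_strength(0.0, params)
    c_half = inhibition_strength(delta_f / 2.0, params)
    c_full = inhibition_strength(delta_f, params)

    u = np.array([
        params.beta_e * state.d[0] * state.e[0]
        - c0 * rA - c_half * rAB - c_full * rB
        - params.g * state.a[0] + iA + state.chi[0],
        params.beta_e * state.d[1] * state.e[1]
        - c0 * rAB - c_half * (rA + rB)
        - params.g * state.a[1] + iAB + state.chi[1],
        params.beta_e * state.d[2] * state.e[2]
        - c0 * rB - c_half * rAB - c_full * rA
        - params.g * state.a[2] + iB + state.chi[2],
    ])
    F = firing_rate(u, params)
    return NetworkState(
        r=(-state.r + F) / params.tau_r,
        a=(-state.a + state.r) / params.tau_a,
        e=(-state.e + state.r) / params.tau_e,
        d=(-state.d + (1.0 - params.kappa * state.r)) / params.tau_d,
        chi=-state.chi / params.tau_X,
    )
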