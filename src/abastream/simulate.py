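"""Stochastic time integration of the full network.

Euler-Maruyama with a fixed step for the deterministic variables and an
exact update for the Ornstein-Uhlenbeck noise.  The inner loop is compiled
with numba; trajectories are a deterministic function of
``(stimulus, parameters, dt, seed)``.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .model_core import ModelParameters, StimulusDescriptor, STATE_VARS
from .stimulus import unit_inputs

__all__ = ["ou_step", "run_trial", "SimulationTrace", "spawn_trial_seeds"]

#: default integration step: one tenth of the cortical timescale tau_r
DEFAULT_DT = 0.001


def ou_step(chi, dt: float, params: ModelParameters, normal_draw):
    """One exact update of the OU noise ``chi`` over a step ``dt``.

    The process ``tau_X chi' = -chi + ...`` has stationary standard
    deviation ``gamma``; the exact discretization is

    ``chi(t+dt) = chi(t) e^{-dt/tau_X} + gamma sqrt(1 - e^{-2dt/tau_X}) z``

    with ``z`` a standard normal draw.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    decay = np.exp(-dt / params.tau_X)
    sd = params.gamma * np.sqrt(1.0 - decay ** 2)
    return chi * decay + sd * np.asarray(normal_draw)


@dataclass
class SimulationTrace:
    """Time-sampled state history of one trial.

    ``states`` has one row per sample and columns ordered as
    :data:`abastream.model_core.STATE_VARS` (full record) or just the three
    firing rates ``r_A, r_AB, r_B`` (rates-only record used by batch sweeps).
    """

    times: np.ndarray
    states: np.ndarray
    columns: tuple
    stim: StimulusDescriptor
    params: ModelParameters
    seed: int
    dt: float

    @property
    def rates(self) -> np.ndarray:
        """Firing rates as an ``(n, 3)`` array ordered (A, AB, B)."""
        i = [self.columns.index(c) for c in ("r_A", "r_AB", "r_B")]
        return self.states[:, i]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.columns))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> dict:
        p = self.params.to_dict()
        blob = json.dumps(p, sort_keys=True).encode()
        return {
            "seed": int(self.seed),
            "dt": self.dt,
            "stim": {"delta_f": self.stim.delta_f, "pr": self.stim.pr,
                     "duration": self.stim.duration},
            "params": p,
            "params_sha1": hashlib.sha1(blob).hexdigest(),
        }

    def swapped_AB(self) -> "SimulationTrace":
        """Trace with the A and B units exchanged (for symmetry checks)."""
        cols = list(self.columns)
        order = []
        for c in cols:
            if c.endswith("_A"):
                order.append(cols.index(c[:-2] + "_B"))
            elif c.endswith("_B"):
                order.append(cols.index(c[:-2] + "_A"))
            else:
                order.append(cols.index(c))
        return SimulationTrace(self.times, self.states[:, order],
                               self.columns, self.stim, self.params,
                               self.seed, self.dt)


@njit(cache=True)
def _integrate(drives, dt, theta_F, k_F, g, beta_i, sigma_i_sq2, global_inh,
               beta_e, kappa, tau_r, tau_a, tau_e, tau_d, delta_f,
               chi_decay, chi_sd, innovations, chi0, out, full):
    """Compiled Euler-Maruyama loop.

    ``drives`` is ``(n, 3)``; ``out`` is ``(n, 3)`` receiving the firing
    rates; ``full`` is ``(n, 12)`` receiving (a, e, d, chi) when its length
    matches ``n`` (otherwise only rates are recorded).
    """
    n = drives.shape[0]
    record_full = full.shape[0] == n

    if global_inh:
        c_half = beta_i
        c_full = beta_i
    else:
        c_half = beta_i * np.exp(-(delta_f * 0.5) ** 2 / sigma_i_sq2)
        c_full = beta_i * np.exp(-delta_f ** 2 / sigma_i_sq2)
    c0 = beta_i

    r = np.zeros(3)
    a = np.zeros(3)
    e = np.zeros(3)
    d = np.ones(3)
    chi = chi0.copy()

    for i in range(n):
        out[i, 0] = r[0]
        out[i, 1] = r[1]
        out[i, 2] = r[2]
        if record_full:
            for k in range(3):
                full[i, k] = a[k]
                full[i, 3 + k] = e[k]
                full[i, 6 + k] = d[k]
                full[i, 9 + k] = chi[k]
        if i == n - 1:
            break

        uA = (beta_e * d[0] * e[0] - c0 * r[0] - c_half * r[1]
              - c_full * r[2] - g * a[0] + drives[i, 0] + chi[0])
        uAB = (beta_e * d[1] * e[1] - c0 * r[1] - c_half * (r[0] + r[2])
               - g * a[1] + drives[i, 1] + chi[1])
        uB = (beta_e * d[2] * e[2] - c0 * r[2] - c_half * r[1]
              - c_full * r[0] - g * a[2] + drives[i, 2] + chi[2])

        fA = 1.0 / (1.0 + np.exp(k_F * (theta_F - uA)))
        fAB = 1.0 / (1.0 + np.exp(k_F * (theta_F - uAB)))
        fB = 1.0 / (1.0 + np.exp(k_F * (theta_F - uB)))

        for k in range(3):
            a[k] += dt * (-a[k] + r[k]) / tau_a
            e[k] += dt * (-e[k] + r[k]) / tau_e
            d[k] += dt * (-d[k] + 1.0 - kappa * r[k]) / tau_d
        r[0] += dt * (-r[0] + fA) / tau_r
        r[1] += dt * (-r[1] + fAB) / tau_r
        r[2] += dt * (-r[2] + fB) / tau_r
        for k in range(3):
            chi[k] = chi[k] * chi_decay + chi_sd * innovations[i, k]

        for k in range(3):
            if not np.isfinite(r[k]):
                return i
    return -1


def run_trial(stim: StimulusDescriptor, params: ModelParameters,
              dt: float = DEFAULT_DT, seed: int = 0,
              record: str = "full", drives: np.ndarray | None = None,
              ) -> SimulationTrace:
    """Integrate one trial and return its :class:`SimulationTrace`.

    Initial conditions: rates, adaptation and excitation at 0, depression at
    1, noise drawn from its stationary distribution.  ``record="rates"``
    stores only the three firing rates (sufficient for percept decoding and
    much lighter for batch sweeps).  ``drives`` may carry a precomputed
    per-unit input array to reuse across noise realizations of the same
    stimulus.
    """
    if dt > params.tau_r / 10.0 + 1e-12:
        raise ValueError("dt must not exceed tau_r / 10")
    n = int(round(stim.duration / dt)) + 1
    t_grid = np.arange(n) * dt
    if drives is None:
        drives = unit_inputs(stim, params, t_grid)
    elif drives.shape != (n, 3):
        raise ValueError("precomputed drives have the wrong shape")

    rng = np.random.default_rng(seed)
    chi0 = rng.normal(0.0, params.gamma, size=3)
    innovations = rng.standard_normal((n - 1, 3)) if n > 1 else np.zeros((0, 3))
    chi_decay = np.exp(-dt / params.tau_X)
    chi_sd = params.gamma * np.sqrt(1.0 - chi_decay ** 2)

    sigma_i_sq2 = (2.0 * params.sigma_i ** 2
                   if np.isfinite(params.sigma_i) else np.inf)
    global_inh = (params.inhibition_mode == "global"
                  or not np.isfinite(params.sigma_i))

    rates = np.empty((n, 3))
    full = np.empty((n, 12)) if record == "full" else np.empty((0, 12))
    bad = _integrate(
        np.ascontiguousarray(drives), dt, params.theta_F, params.k_F,
        params.g, params.beta_i, sigma_i_sq2, global_inh, params.beta_e,
        params.kappa, params.tau_r, params.tau_a, params.tau_e, params.tau_d,
        stim.delta_f, chi_decay, chi_sd, innovations, chi0, rates, full)
    if bad >= 0:
        raise FloatingPointError(
            f"integration diverged at t = {bad * dt:.3f} s "
            f"(seed {seed}, delta_f {stim.delta_f}, PR {stim.pr})")

    if record == "full":
        states = np.column_stack([
            rates[:, 0], rates[:, 1], rates[:, 2],
            full[:, 0], full[:, 1], full[:, 2],
            full[:, 3], full[:, 4], full[:, 5],
            full[:, 6], full[:, 7], full[:, 8],
            full[:, 9], full[:, 10], full[:, 11],
        ])
        columns = STATE_VARS
    elif record == "rates":
        states = rates
        columns = ("r_A", "r_AB", "r_B")
    else:
        raise ValueError("record must be 'full' or 'rates'")
    return SimulationTrace(times=t_grid, states=states, columns=columns,
                           stim=stim, params=params, seed=seed, dt=dt)


def spawn_trial_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-trial seeds from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]
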