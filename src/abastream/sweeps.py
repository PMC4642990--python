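"""Batch experiments over stimulus parameters.

Covers the frequency-difference sweep at fixed presentation rate (the
"X diagram" of integrated vs segregated mean durations), the (PR, Δf)
van Noorden grid of proportion-integrated, equidominance location, and the
generalized-Levelt measure η.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import ModelParameters, StimulusDescriptor
from .simulate import DEFAULT_DT, run_trial, spawn_trial_seeds
from .stimulus import unit_inputs
from .decode import INTEGRATED, decode_trace, extract_durations

__all__ = [
    "EXPERIMENT_DF_VALUES", "run_batch", "proportion_integrated",
    "df_sweep", "DfSweepResult", "vn_grid", "ambiguous_band_width",
    "dominance_fraction", "find_equidominance", "levelt_measure",
]

#: the eight frequency-difference conditions (semitones) of the experiment
EXPERIMENT_DF_VALUES = (1, 2, 3, 5, 7, 9, 11, 15)


def run_batch(params: ModelParameters, stim: StimulusDescriptor,
              n_trials: int, seed: int, dt: float = DEFAULT_DT) -> list:
    """Decode ``n_trials`` independent noise realizations of one stimulus.

    The per-unit drive is precomputed once and shared across trials; each
    trial gets an independent substream seed derived from ``seed``.
    """
    n = int(round(stim.duration / dt)) + 1
    drives = unit_inputs(stim, params, np.arange(n) * dt)
    tracks = []
    for s in spawn_trial_seeds(seed, n_trials):
        trace = run_trial(stim, params, dt=dt, seed=s, record="rates",
                          drives=drives)
        tracks.append(decode_trace(trace))
    return tracks


def proportion_integrated(tracks) -> float:
    """Total integrated time over total classified time, pooled over trials.

    Uses each track's full span (no first/last exclusions): the proportion
    is a time budget, not a duration statistic.
    """
    if not tracks:
        raise ValueError("empty track batch")
    v_int = sum(t.time_in(INTEGRATED) for t in tracks)
    total = sum(t.span for t in tracks)
    if total == 0:
        raise ValueError("tracks contain no classified time")
    return v_int / total


@dataclass
class DfSweepResult:
    """Frequency-difference sweep summary at fixed presentation rate.

    ``frame`` is tidy with one row per (delta_f, percept): trial count,
    retained-duration count, raw mean (s) and mean normalized by the global
    mean duration ``t_glob``.  ``u_int`` maps delta_f to proportion
    integrated; ``durations`` keeps the pooled per-condition samples.
    """

    pr: float
    df_values: tuple
    frame: pd.DataFrame
    u_int: dict
    t_glob: float
    durations: dict
    seed: int
    n_trials: int

    def mean_durations(self, normalized: bool = True) -> pd.DataFrame:
        """Wide table of integrated / segregated mean durations per Δf."""
        col = "norm_mean" if normalized else "mean_s"
        return self.frame.pivot(index="delta_f", columns="percept",
                                values=col)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def manifest(self) -> dict:
        return {"pr": self.pr, "df_values": list(self.df_values),
                "n_trials": self.n_trials, "seed": self.seed,
                "t_glob": self.t_glob}


def df_sweep(params: ModelParameters, df_values=EXPERIMENT_DF_VALUES,
             pr: float = 8.0, n_trials: int = 50, duration: float = 240.0,
             seed: int = 0, dt: float = DEFAULT_DT,
             norm_df_values=None) -> DfSweepResult:
    """Sweep Δf at fixed PR; pool subsequent durations per condition.

    First and final (incomplete) durations are excluded.  The global mean
    duration ``t_glob`` pools both percept types across the conditions in
    ``norm_df_values`` (default: the experimental eight that are present in
    the sweep, falling back to all swept values) and normalizes the
    per-condition means, mirroring the behavioral analysis.
    """
    df_values = tuple(float(x) for x in df_values)
    ss = np.random.SeedSequence(seed)
    point_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(len(df_values))]

    durations, u_int = {}, {}
    for df, pseed in zip(df_values, point_seeds):
        stim = StimulusDescriptor(delta_f=df, pr=pr, duration=duration)
        tracks = run_batch(params, stim, n_trials, pseed, dt=dt)
        u_int[df] = proportion_integrated(tracks)
        durations[df] = pd.concat(
            [extract_durations(t) for t in tracks], ignore_index=True)

    if norm_df_values is None:
        norm_df_values = [d for d in df_values if d in EXPERIMENT_DF_VALUES]
        if not norm_df_values:
            norm_df_values = list(df_values)
    pool = pd.concat([durations[d] for d in norm_df_values], ignore_index=True)
    t_glob = float(pool["duration_s"].mean()) if len(pool) else np.nan

    rows = []
    for df in df_values:
        for percept, grp in durations[df].groupby("percept"):
            m = float(grp["duration_s"].mean())
            rows.append({"delta_f": df, "percept": percept, "pr": pr,
                         "n_trials": n_trials, "n_durations": len(grp),
                         "mean_s": m, "sd_s": float(grp["duration_s"].std(ddof=1)),
                         "norm_mean": m / t_glob, "u_int": u_int[df]})
    frame = pd.DataFrame(rows).sort_values(["delta_f", "percept"],
                                           ignore_index=True)
    return DfSweepResult(pr=pr, df_values=df_values, frame=frame,
                         u_int=u_int, t_glob=t_glob, durations=durations,
                         seed=seed, n_trials=n_trials)


def find_equidominance(df_values, u_int) -> float | None:
    """Δf where proportion integrated crosses 0.5 (linear interpolation).

    ``u_int`` may be a mapping or a sequence aligned with ``df_values``.
    Returns the first crossing (direction-agnostic) or ``None``.
    """
    xs = np.asarray(sorted(df_values), dtype=float)
    us = np.array([u_int[x] if isinstance(u_int, dict) else
                   u_int[list(df_values).index(x)] for x in xs], dtype=float)
    diff = us - 0.5
    for i in range(len(xs) - 1):
        if diff[i] == 0.0:
            return float(xs[i])
        if diff[i] * diff[i + 1] < 0:
            frac = diff[i] / (diff[i] - diff[i + 1])
            return float(xs[i] + frac * (xs[i + 1] - xs[i]))
    if diff[-1] == 0.0:
        return float(xs[-1])
    return None


def levelt_measure(df_values, t1, t2, s_eq) -> dict:
    """η(S) = (T1(S) + T2(S) - 2 T_eq) / T_eq per swept value.

    ``t1``/``t2`` map each swept value to the two percepts' mean durations;
    ``T_eq`` is taken as the branch value at the equidominance point
    ``s_eq`` (the branches cross there, so either works; the interpolated
    crossing value of branch 1 is used).  η is positive when the stronger
    percept's duration grows more than the weaker's shrinks away from
    equidominance.
    """
    xs = np.asarray(sorted(df_values), dtype=float)
    a1 = np.array([t1[x] for x in xs], dtype=float)
    a2 = np.array([t2[x] for x in xs], dtype=float)
    t_eq = float(np.interp(s_eq, xs, a1))
    if not t_eq > 0:
        raise ValueError("T_eq must be positive")
    eta = (a1 + a2 - 2.0 * t_eq) / t_eq
    return {"s_eq": float(s_eq), "t_eq": t_eq,
            "eta": dict(zip(xs.tolist(), eta.tolist()))}


def eta_from_sweep(sweep: DfSweepResult) -> dict:
    """Convenience: equidominance + η directly from a Δf sweep."""
    s_eq = find_equidominance(sweep.df_values, sweep.u_int)
    if s_eq is None:
        raise ValueError("proportion integrated never crosses 0.5")
    wide = sweep.mean_durations(normalized=True)
    t1 = wide["integrated"].to_dict()
    t2 = wide["segregated"].to_dict()
    return levelt_measure(sweep.df_values, t1, t2, s_eq)


def vn_grid(params: ModelParameters, pr_values, df_values,
            n_trials: int = 12, duration: float = 240.0, seed: int = 0,
            dt: float = DEFAULT_DT) -> pd.DataFrame:
    """Proportion integrated over a (PR, Δf) grid — the van Noorden map.

    Returns a tidy frame with one row per grid point: ``pr, delta_f,
    u_int, n_trials, mean_int_s, mean_seg_s, region`` where ``region``
    labels integrated (u > 0.95), segregated (u < 0.05) or ambiguous.
    """
    pr_values = tuple(float(x) for x in pr_values)
    df_values = tuple(float(x) for x in df_values)
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(s.generate_state(1)[0] % (2 ** 31))
                 for s in ss.spawn(len(pr_values) * len(df_values)))
    rows = []
    for pr in pr_values:
        for df in df_values:
            stim = StimulusDescriptor(delta_f=df, pr=pr, duration=duration)
            tracks = run_batch(params, stim, n_trials, next(seeds), dt=dt)
            u = proportion_integrated(tracks)
            durs = pd.concat([extract_durations(t) for t in tracks],
                             ignore_index=True)
            means = durs.groupby("percept")["duration_s"].mean()
            rows.append({
                "pr": pr, "delta_f": df, "u_int": u, "n_trials": n_trials,
                "mean_int_s": float(means.get("integrated", np.nan)),
                "mean_seg_s": float(means.get("segregated", np.nan)),
                "region": ("integrated" if u > 0.95 else
                           "segregated" if u < 0.05 else "ambiguous"),
            })
    return pd.DataFrame(rows)


def ambiguous_band_width(grid: pd.DataFrame, pr: float,
                         lo: float = 0.05, hi: float = 0.95) -> float:
    """Δf-extent of the ambiguous region (lo < U_int < hi) at one PR.

    Boundaries are linearly interpolated between grid points; a boundary
    outside the sampled range clamps to the range edge.
    """
    sub = grid[grid["pr"] == pr].sort_values("delta_f")
    xs = sub["delta_f"].to_numpy(dtype=float)
    us = sub["u_int"].to_numpy(dtype=float)
    if xs.size < 2:
        raise ValueError(f"need at least two delta_f samples at PR={pr}")

    def crossing(level):
        d = us - level
        for i in range(len(xs) - 1):
            if d[i] == 0.0:
                return xs[i]
            if d[i] * d[i + 1] < 0:
                return xs[i] + d[i] / (d[i] - d[i + 1]) * (xs[i + 1] - xs[i])
        return None

    upper = crossing(hi)   # integrated boundary (U falls through hi)
    lower = crossing(lo)   # segregated boundary (U falls through lo)
    left = upper if upper is not None else xs[0]
    right = lower if lower is not None else xs[-1]
    return float(max(right - left, 0.0))


def dominance_fraction(grid: pd.DataFrame, lo: float = 0.05,
                       hi: float = 0.95) -> float:
    """Fraction of grid points where one percept dominates (U beyond lo/hi)."""
    u = grid["u_int"].to_numpy(dtype=float)
    return float(np.mean((u > hi) | (u < lo)))


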