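"""Percept decoding: firing-rate traces -> percept labels and durations.

The three rate traces are smoothed with a 50 ms moving average; the output
is classified *integrated* whenever the smoothed central rate exceeds the
mean of the smoothed peripheral rates, and *segregated* otherwise.  Runs of
a constant label are dominance durations; the final run of every trial is
incomplete (cut off by the end of the trial) and the first run covers the
build-up phase, so both are normally excluded from statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SimulationTrace

__all__ = ["smooth", "classify", "debounce", "segment", "extract_durations",
           "decode_trace", "PerceptTrack", "INTEGRATED", "SEGREGATED"]

INTEGRATED = "integrated"
SEGREGATED = "segregated"

#: moving-average window (seconds) used for the readout
SMOOTH_WINDOW = 0.050


@dataclass
class PerceptTrack:
    """Decoded label sequence for one trial.

    ``onsets``/``offsets``/``labels`` describe maximal runs of one percept;
    labels alternate by construction.  ``foreground`` optionally carries the
    secondary A-vs-B foreground label for segregated runs (not used in any
    statistic).
    """

    onsets: np.ndarray
    offsets: np.ndarray
    labels: list
    foreground: list = field(default_factory=list)

    @property
    def durations(self) -> np.ndarray:
        return self.offsets - self.onsets

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def span(self) -> float:
        return float(self.offsets[-1] - self.onsets[0]) if self.n else 0.0

    def time_in(self, label: str) -> float:
        mask = np.array([lb == label for lb in self.labels])
        return float(self.durations[mask].sum()) if self.n else 0.0

    def to_frame(self) -> pd.DataFrame:
        n = self.n
        return pd.DataFrame({
            "onset_s": self.onsets,
            "offset_s": self.offsets,
            "duration_s": self.durations,
            "percept": self.labels,
            "is_first": [i == 0 for i in range(n)],
            "is_incomplete": [i == n - 1 for i in range(n)],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def smooth(x: np.ndarray, window: float, dt: float) -> np.ndarray:
    """Centered moving average with window truncated at the boundaries.

    ``window`` and ``dt`` are in seconds; the window spans
    ``round(window / dt) + 1`` samples (forced odd so it is centered).
    Output length equals input length; a constant signal is unchanged,
    including at the edges.
    """
    if window < dt:
        raise ValueError("window must be at least one sample wide")
    x = np.asarray(x, dtype=float)
    m = int(round(window / dt)) + 1
    if m % 2 == 0:
        m += 1
    half = m // 2
    n = x.shape[0]
    csum = np.zeros((n + 1,) + x.shape[1:])
    np.cumsum(x, axis=0, out=csum[1:])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo).reshape(-1, *([1] * (x.ndim - 1)))


def classify(smoothed: np.ndarray) -> np.ndarray:
    """Pointwise labels from smoothed rates ``(n, 3)`` ordered (A, AB, B).

    True marks *integrated*: ``r_AB > (r_A + r_B) / 2``.  Exact ties keep
    the previous sample's label (one-sample hysteresis; the competition
    produces steep crossings, so ties only arise at machine precision).
    """
    rA, rAB, rB = smoothed[:, 0], smoothed[:, 1], smoothed[:, 2]
    margin = rAB - 0.5 * (rA + rB)
    labels = margin > 0
    ties = np.flatnonzero(margin == 0.0)
    for i in ties:
        if i > 0:
            labels[i] = labels[i - 1]
    return labels


def debounce(labels: np.ndarray, dt: float, min_duration: float) -> np.ndarray:
    """Merge label runs shorter than ``min_duration`` into the ongoing percept.

    The competition produces occasional sub-triplet flickers of the margin
    around a switch; dominance shorter than one stimulus cycle cannot be
    perceived, so runs below ``min_duration`` (conventionally one triplet,
    ``4 / PR``) are absorbed into the preceding percept, shortest first.
    The first and final runs of a trial are never absorbed (they are
    excluded from statistics anyway).
    """
    lab = np.asarray(labels, dtype=bool).copy()
    min_n = int(round(min_duration / dt))
    if min_n <= 1 or lab.size == 0:
        return lab
    while True:
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [lab.size]])
        lens = ends - starts
        interior = np.arange(1, len(starts) - 1)
        short = interior[lens[interior] < min_n]
        if short.size == 0:
            return lab
        i = short[np.argmin(lens[short])]
        lab[starts[i]:ends[i]] = lab[starts[i] - 1]


def segment(labels: np.ndarray, dt: float,
            foreground_margin: np.ndarray | None = None) -> PerceptTrack:
    """Group a pointwise boolean label series into maximal percept runs."""
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    if n == 0:
        return PerceptTrack(np.array([]), np.array([]), [])
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    names = [INTEGRATED if labels[s] else SEGREGATED for s in starts]
    fg = []
    for s, e in zip(starts, ends):
        if labels[s] or foreground_margin is None:
            fg.append(None)
        else:
            fg.append("A" if foreground_margin[s:e].mean() >= 0 else "B")
    return PerceptTrack(onsets=starts * dt, offsets=ends * dt,
                        labels=names, foreground=fg)


def decode_trace(trace: SimulationTrace, window: float = SMOOTH_WINDOW,
                 min_switch_duration: float | None = None) -> PerceptTrack:
    """Full decoding pipeline for one simulation trace.

    ``min_switch_duration`` is the debounce threshold; ``None`` selects one
    triplet cycle (``4 / PR``) of the trace's stimulus.  Pass 0 to disable.
    """
    if min_switch_duration is None:
        min_switch_duration = trace.stim.triplet_period
    sm = smooth(trace.rates, window, trace.dt)
    labels = debounce(classify(sm), trace.dt, min_switch_duration)
    return segment(labels, trace.dt, foreground_margin=sm[:, 0] - sm[:, 2])


def extract_durations(track: PerceptTrack, exclude_first: bool = True,
                      min_duration: float = 0.0) -> pd.DataFrame:
    """Durations retained for statistics, as columns ``duration_s, percept``.

    Always drops the final (incomplete) duration; drops the first duration
    when ``exclude_first``; optionally drops durations shorter than
    ``min_duration`` (0.5 s — one triplet — is the convention for
    experimental key presses; model output uses 0 by default).  A track with
    fewer than three runs yields an empty frame: nothing survives the
    exclusions.
    """
    df = track.to_frame()
    keep = ~df["is_incomplete"]
    if exclude_first:
        keep &= ~df["is_first"]
    if min_duration > 0:
        keep &= df["duration_s"] >= min_duration
    return df.loc[keep, ["duration_s", "percept"]].reset_index(drop=True)
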