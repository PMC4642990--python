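"""Pulsatile input drive for ABA- triplet sequences.

The drive mimics onset-and-plateau responses of primary auditory cortex to
short pure tones: each tone onset launches a double alpha-function impulse
(a fast, full-amplitude onset component plus a slower, smaller plateau
component).  Within each triplet cycle of length ``4/PR`` the A tone sounds
in slots 1 and 3, the B tone in slot 2, and slot 4 is silent.  Impulse
responses from successive tones sum where they overlap.
"""

from __future__ import annotations

import numpy as np

from .model_core import ModelParameters, StimulusDescriptor, input_gain

__all__ = ["tone_impulse", "tone_onsets", "triplet_train", "unit_inputs"]

#: drive below this value is treated as zero when truncating the impulse
_IMPULSE_CUTOFF = 1e-8


def tone_impulse(t, params: ModelParameters):
    """Single-tone onset response at time ``t`` (seconds) after tone onset.

    ``H(t) [ (e^2/alpha1^2) t^2 e^{-2t/alpha1}
             + Lambda2 (e^2/alpha2^2) t^2 e^{-2t/alpha2} ]``

    Each alpha component ``(e^2/alpha^2) t^2 e^{-2t/alpha}`` peaks with
    value 1 at ``t = alpha``, so the onset component reaches 1 at
    ``alpha1`` and the plateau component reaches ``Lambda2`` at ``alpha2``.
    Zero for ``t < 0``.
    """
    t = np.asarray(t, dtype=float)
    e2 = np.exp(2.0)
    with np.errstate(invalid="ignore"):
        first = e2 / params.alpha1 ** 2 * t ** 2 * np.exp(-2.0 * t / params.alpha1)
        second = params.Lambda2 * e2 / params.alpha2 ** 2 * t ** 2 * np.exp(
            -2.0 * t / params.alpha2)
    out = np.where(t >= 0.0, first + second, 0.0)
    return float(out) if out.ndim == 0 else out


def impulse_support(params: ModelParameters) -> float:
    """Time after onset beyond which the impulse is below the cutoff."""
    # the slow component dominates the tail: Lambda2 e^2/a2^2 t^2 e^{-2t/a2}
    t = 5.0 * params.alpha2
    while tone_impulse(t, params) > _IMPULSE_CUTOFF:
        t *= 1.5
    return t


def tone_onsets(which: str, stim: StimulusDescriptor) -> np.ndarray:
    """Onset times of the A or B tones within ``[0, duration)``.

    A tones at triplet phases 0 and ``2/PR``, B tones at phase ``1/PR``.
    """
    period = stim.triplet_period
    n_triplets = int(np.ceil(stim.duration / period))
    base = np.arange(n_triplets) * period
    if which == "A":
        onsets = np.sort(np.concatenate([base, base + 2.0 / stim.pr]))
    elif which == "B":
        onsets = base + 1.0 / stim.pr
    else:
        raise ValueError("which must be 'A' or 'B'")
    return onsets[onsets < stim.duration]


def triplet_train(which: str, stim: StimulusDescriptor,
                  t_grid: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Summed impulse drive of the A or B tone train on a uniform grid.

    The impulse is evaluated once on the grid and added at each onset index,
    truncated where it falls below ``1e-8`` (about one second after onset).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    n = t_grid.size
    if n == 0 or stim.duration == 0:
        return np.zeros(n)
    dt = t_grid[1] - t_grid[0] if n > 1 else 1.0
    support = impulse_support(params)
    m = min(n, int(np.ceil(support / dt)) + 1)
    template = tone_impulse(np.arange(m) * dt, params)

    train = np.zeros(n)
    for onset in tone_onsets(which, stim):
        # onsets align with the grid only when onset/dt is integral; round to
        # the nearest sample (grid is required to be uniform)
        i0 = int(round((onset - t_grid[0]) / dt))
        if i0 >= n:
            continue
        i1 = min(n, i0 + m)
        train[i0:i1] += template[: i1 - i0]
    return train


def unit_inputs(stim: StimulusDescriptor, params: ModelParameters,
                t_grid: np.ndarray) -> np.ndarray:
    """Per-unit drive array of shape ``(len(t_grid), 3)`` for units (A, AB, B).

    Every input pathway is scaled by the tonotopic spread function ``w``
    (so a unit's own tone arrives with the full input amplitude
    ``w(0) = I_p``):

    * ``drive_A  = w(0) * train_A``
    * ``drive_AB = w(delta_f / 2) * (train_A + train_B)``
    * ``drive_B  = w(0) * train_B``

    Peripheral units are driven by their preferred tone only: the
    integrated percept's dominance at small frequency separations rests on
    the peripheral units having to bridge their 250 ms input gaps on the
    slow-excitation timescale alone, while the central unit collects three
    evenly spaced pulses per triplet.  A cross term feeding the opposite
    tone to a peripheral unit at gain ``w(delta_f)`` fills those gaps and
    abolishes integrated dominance; it is available for exploration via
    ``params.peripheral_cross_gain`` (a multiplier on ``w(delta_f)``,
    0 by default).
    """
    train_A = triplet_train("A", stim, t_grid, params)
    train_B = triplet_train("B", stim, t_grid, params)
    w_own = input_gain(0.0, params)
    w_half = input_gain(stim.delta_f / 2.0, params)
    cross = params.peripheral_cross_gain * input_gain(stim.delta_f, params)
    return np.column_stack([
        w_own * train_A + cross * train_B,
        w_half * (train_A + train_B),
        w_own * train_B + cross * train_A,
    ])
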