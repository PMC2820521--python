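"""Calcium and dopamine input waveforms.

Both inputs are prescribed concentration time courses (the glutamate →
calcium influx machinery is upstream of this model). Transients are
alpha functions; a calcium spike train combines its pulses with a
pointwise maximum rather than temporal summation, matching calcium
imaging of striatal projection neurons, and dopamine repeats are
combined the same way for symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlphaPulse",
    "CalciumProtocol",
    "DopamineProtocol",
    "alpha",
    "calcium_waveform",
    "dopamine_waveform",
]

#: Default alpha-function time constants (s). The calcium value sits in
#: the tens-of-milliseconds range of striatal spine calcium transients;
#: the dopamine value reflects the ~100 ms striatal dopamine transient
#: measured by fast-scan voltammetry (transients decaying over a few
#: hundred ms to ~1 s).
TAU_CA = 0.03
TAU_DA = 0.50


@dataclass(frozen=True)
class AlphaPulse:
    """A normalized alpha-function pulse with time constant tau (s)."""

    tau: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


def alpha(t, pulse: AlphaPulse):
    """Normalized alpha function ((t−t0)/τ)·exp(1−(t−t0)/τ), zero before t0.

    Peaks at exactly 1 when t = t0 + τ.
    """
    x = (np.asarray(t, float) - pulse.t0) / pulse.tau
    out = np.where(x > 0, x * np.exp(np.clip(1.0 - x, -700, 700)), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CalciumProtocol:
    """Intracellular calcium input: spike trains of alpha transients.

    Defaults are the study conditions: 8 spikes at 10 ms inter-spike
    interval (100 Hz), repeated 6 times at 10 s intervals; basal calcium
    0.06 µM. ``ca_amp`` is the weak (1 µM) amplitude by default; the
    strong condition uses 10 µM.
    """

    ca_basal: float = 0.06
    ca_amp: float = 1.0
    n_spikes: int = 8
    isi: float = 0.01
    n_repeats: int = 6
    repeat_interval: float = 10.0
    tau_ca: float = TAU_CA
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if min(self.ca_basal, self.ca_amp) < 0 or self.tau_ca <= 0:
            raise ValueError("calcium protocol values must be non-negative, tau > 0")
        if self.n_spikes < 1 or self.n_repeats < 1 or self.isi <= 0:
            raise ValueError("need n_spikes, n_repeats >= 1 and isi > 0")

    def spike_times(self) -> np.ndarray:
        reps = self.t_start + self.repeat_interval * np.arange(self.n_repeats)
        spikes = self.isi * np.arange(self.n_spikes)
        return (reps[:, None] + spikes[None, :]).ravel()

    def active_windows(self) -> list[tuple[float, float]]:
        """Intervals where the transient is non-negligible (for solvers)."""
        span = (self.n_spikes - 1) * self.isi + 12 * self.tau_ca
        return [(self.t_start + k * self.repeat_interval,
                 self.t_start + k * self.repeat_interval + span)
                for k in range(self.n_repeats)]


def calcium_waveform(t, p: CalciumProtocol):
    """Calcium concentration at time(s) t: basal + amp·max over spikes."""
    tt = np.atleast_1d(np.asarray(t, float))
    env = np.zeros_like(tt)
    for ts in p.spike_times():
        env = np.maximum(env, alpha(tt, AlphaPulse(p.tau_ca, ts)))
    out = p.ca_basal + p.ca_amp * env
    return out if np.ndim(t) else float(out[0])


@dataclass(frozen=True)
class DopamineProtocol:
    """Extracellular dopamine input: one alpha transient per repeat.

    ``offset_vs_calcium`` shifts every dopamine pulse relative to the
    matching calcium train onset (positive: dopamine follows calcium).
    Basal dopamine defaults to 0.01 µM (tonic level); depletion sets
    both basal and amplitude to zero.
    """

    da_basal: float = 0.01
    da_amp: float = 1.0
    n_repeats: int = 6
    repeat_interval: float = 10.0
    tau_da: float = TAU_DA
    offset_vs_calcium: float = 0.0
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if self.da_basal < 0 or self.da_amp < 0 or self.tau_da <= 0:
            raise ValueError("dopamine protocol values must be non-negative, tau > 0")

    def pulse_times(self) -> np.ndarray:
        return (self.t_start + self.offset_vs_calcium
                + self.repeat_interval * np.arange(self.n_repeats))

    def active_windows(self) -> list[tuple[float, float]]:
        return [(ts, ts + 12 * self.tau_da) for ts in self.pulse_times()]


def dopamine_waveform(t, p: DopamineProtocol):
    """Dopamine concentration at time(s) t: basal + amp·max over pulses."""
    tt = np.atleast_1d(np.asarray(t, float))
    env = np.zeros_like(tt)
    for ts in p.pulse_times():
        env = np.maximum(env, alpha(tt, AlphaPulse(p.tau_da, ts)))
    out = p.da_basal + p.da_amp * env
    return out if np.ndim(t) else float(out[0])


def constant_protocols(ca_basal: float = 0.06, da_basal: float = 0.01
                       ) -> tuple[CalciumProtocol, DopamineProtocol]:
    """Zero-amplitude protocols holding both inputs at basal levels."""
    ca = CalciumProtocol(ca_basal=ca_basal, ca_amp=0.0) if ca_basal >= 0 else None
    da = DopamineProtocol(da_basal=da_basal, da_amp=0.0)
    return ca, da
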