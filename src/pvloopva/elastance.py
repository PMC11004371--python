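"""Time-varying elastance waveforms and the right-atrial pacing clock.

Each chamber's pressure-volume behaviour is P(t) = E(t) * (V(t) - V0), with
E(t) swinging periodically between E_min (diastole) and E_max (end systole).
The activation waveform is a double raised cosine: a half-cosine rise over
the systolic interval followed by a half-cosine fall over half that interval,
returning to zero for the remainder of the cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import ChamberParams

__all__ = [
    "PacingSchedule",
    "pacing_schedule",
    "normalized_activation",
    "chamber_elastance",
    "chamber_pressure",
]

#: Relaxation lasts this fraction of the systolic interval.
RELAX_FRACTION = 0.5

#: Exponent < 1 skews the systolic rise so that early contraction is brisk
#: (short isovolumic contraction time) while the peak stays smooth at 1.
RISE_EXPONENT = 0.42


@dataclass(frozen=True)
class PacingSchedule:
    """Regular pacing onsets at a fixed rate, starting at t = 0."""

    heart_rate: float  # bpm
    beat_onsets: np.ndarray  # s
    beat_period: float  # s

    def __post_init__(self) -> None:
        d = np.diff(self.beat_onsets)
        if d.size and not np.allclose(d, self.beat_period, rtol=0, atol=1e-12):
            raise ValueError("beat onsets must be uniformly spaced at 60/heart_rate")


def pacing_schedule(heart_rate: float, duration: float) -> PacingSchedule:
    """Onsets covering [0, duration]; count = floor(duration*HR/60) + 1."""
    if not (30.0 <= heart_rate <= 220.0):
        raise ValueError(f"heart_rate {heart_rate} outside the paceable range [30, 220] bpm")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    period = 60.0 / heart_rate
    n = int(np.floor(duration / period + 1e-12)) + 1
    return PacingSchedule(heart_rate, np.arange(n) * period, period)


def normalized_activation(phase, chamber: ChamberParams):
    """Dimensionless activation in [0, 1] at a cycle phase in [0, 1).

    Zero before the chamber's activation onset, raised-cosine rise to 1 over
    ``systole_fraction`` of the cycle, raised-cosine fall over half that
    interval, zero through the rest of diastole.  Accepts scalars or arrays.
    """
    phase = np.asarray(phase, dtype=float)
    if np.any(phase < 0) or np.any(phase >= 1):
        warnings.warn("phase outside [0, 1); wrapping modulo 1", stacklevel=2)
        phase = np.mod(phase, 1.0)
    u = np.mod(phase - chamber.activation_onset_fraction, 1.0)
    sf = chamber.systole_fraction
    rf = RELAX_FRACTION * sf
    rising = u < sf
    falling = (u >= sf) & (u < sf + rf)
    act = np.zeros_like(u)
    act[rising] = (0.5 * (1.0 - np.cos(np.pi * u[rising] / sf))) ** RISE_EXPONENT
    act[falling] = 0.5 * (1.0 + np.cos(np.pi * (u[falling] - sf) / rf))
    return act if act.ndim else float(act)


def chamber_elastance(t, chamber: ChamberParams, schedule: PacingSchedule):
    """E(t) = E_min + (E_max - E_min) * activation(phase(t))."""
    phase = np.mod(np.asarray(t, dtype=float), schedule.beat_period) / schedule.beat_period
    return chamber.E_min + (chamber.E_max - chamber.E_min) * normalized_activation(phase, chamber)


def chamber_pressure(volume, E_t, V0_chamber: float, floor: float = -5.0):
    """P = E(t) * (V - V0), clamped below at ``floor`` (deep-occlusion guard)."""
    return np.maximum(np.asarray(E_t, dtype=float) * (np.asarray(volume, dtype=float) - V0_chamber),
                      floor)
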