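"""Beat segmentation and per-beat pressure-volume metrics.

A beat is one pacing interval of the left-ventricular pressure and volume
traces.  End-diastole is the pacing onset sample (the protocol is paced, so
onset is unambiguous); end-systole is the minimum-volume sample; end-systolic
pressure is read at aortic valve closure, detected as the downward
zero-crossing of aortic valve flow, falling back to the pressure at minimum
volume when no flow trace is available (analysis of externally supplied CSV
data).  Stroke work is the area of the closed PV loop; the pressure-volume
area (PVA) adds the end-systolic potential-energy triangle of Suga, and
mechanical efficiency is their ratio as a percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import TimeSeries
from .elastance import PacingSchedule

__all__ = [
    "Beat",
    "BeatMetrics",
    "segment_beats",
    "beat_metrics",
    "stroke_work",
    "pv_area",
    "mechanical_efficiency",
    "dynamic_compliance",
]

MIN_BEAT_SAMPLES = 20


@dataclass
class Beat:
    """One cardiac cycle of the LV trace, with optional aortic context."""

    index: int
    t: np.ndarray  # s
    p_lv: np.ndarray  # mmHg
    v_lv: np.ndarray  # ml
    p_ao: np.ndarray | None = None  # mmHg
    q_av: np.ndarray | None = None  # ml/s
    is_steady_state: bool = False
    is_vco: bool = False

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.p_lv) == len(self.v_lv)):
            raise ValueError("t, p_lv and v_lv must have equal length")
        if len(self.t) < MIN_BEAT_SAMPLES:
            raise ValueError(f"a beat needs >= {MIN_BEAT_SAMPLES} samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("beat time must be strictly increasing")


@dataclass
class BeatMetrics:
    """Scalar PV metrics of a single beat (units in field comments)."""

    EDV: float  # ml
    ESV: float  # ml
    SV: float  # ml
    SW: float  # mmHg*ml
    Pes: float  # mmHg
    LVEDP: float  # mmHg
    PP: float  # mmHg, aortic pulse pressure
    dPdt_max: float  # mmHg/s
    PVA: float = float("nan")  # mmHg*ml, filled once V0 is known
    ME: float = float("nan")  # percent
    Art_ca: float = float("nan")  # ml/mmHg
    index: int = -1
    is_steady_state: bool = False
    is_vco: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "index", "EDV", "ESV", "SV", "SW", "Pes", "LVEDP", "PP",
            "dPdt_max", "PVA", "ME", "Art_ca", "is_steady_state", "is_vco")}


def segment_beats(ts: TimeSeries, schedule: PacingSchedule) -> list[Beat]:
    """Split a trajectory into complete pacing intervals.

    Beats starting at or after ``ts.vco_start`` are flagged as occlusion
    beats; the flags drive which beats enter the relation fits.
    """
    period = schedule.beat_period
    t0, t1 = ts.time[0], ts.time[-1]
    if t1 - t0 < 2 * period - 1e-9:
        raise ValueError("trajectory must span at least two pacing periods")
    # align beat windows with the absolute pacing clock (onsets at k*period);
    # a trailing beat short by at most two samples still counts as complete
    k0 = int(np.ceil(t0 / period - 1e-9))
    dt_med = float(np.median(np.diff(ts.time)))
    beats = []
    eps = 1e-9
    for i, k in enumerate(range(k0, int(np.floor((t1 + 2 * dt_med) / period + eps)))):
        sel = (ts.time >= k * period - eps) & (ts.time < (k + 1) * period - eps)
        if sel.sum() < MIN_BEAT_SAMPLES:
            continue
        onset = k * period
        is_vco = ts.vco_start is not None and onset >= ts.vco_start - eps
        beats.append(Beat(
            index=i,
            t=ts.time[sel],
            p_lv=ts.p_lv[sel],
            v_lv=ts.v_lv[sel],
            p_ao=ts.p_ao[sel] if ts.p_ao is not None else None,
            q_av=ts.q_av[sel] if ts.q_av is not None else None,
            is_steady_state=not is_vco,
            is_vco=is_vco,
        ))
    return beats


def stroke_work(beat: Beat) -> float:
    """Loop area |closed integral of P dV| by the shoelace rule (mmHg*ml)."""
    v, p = beat.v_lv, beat.p_lv
    if abs(v[-1] - v[0]) > 2.0 or abs(p[-1] - p[0]) > 5.0:
        warnings.warn("PV loop is open; closing it by joining last to first sample",
                      stacklevel=2)
    # shoelace over the polygon, implicitly closed
    return 0.5 * abs(float(np.dot(v, np.roll(p, -1)) - np.dot(p, np.roll(v, -1))))


def pv_area(SW: float, Pes: float, ESV: float, v0_for_pva: float) -> float:
    """PVA = SW + potential energy, PE = Pes * (ESV - V0) / 2 (Suga triangle).

    The area under the end-diastolic PV relation is neglected.  If the fitted
    V0 exceeds ESV the triangle is clamped to zero with a warning.
    """
    if ESV <= v0_for_pva:
        warnings.warn("ESV <= V0; clamping potential energy at 0", stacklevel=2)
        return SW
    return SW + 0.5 * Pes * (ESV - v0_for_pva)


def mechanical_efficiency(SW: float, PVA: float) -> float:
    """ME = 100 * SW / PVA (percent)."""
    if PVA <= 0:
        raise ValueError("mechanical efficiency undefined for PVA <= 0")
    return 100.0 * SW / PVA


def dynamic_compliance(SV: float, Pes: float) -> float:
    """Dynamic arterial compliance Art-ca = SV / Pes (ml/mmHg)."""
    if Pes <= 0:
        raise ValueError("dynamic compliance undefined for Pes <= 0")
    return SV / Pes


def _pes_at_valve_closure(beat: Beat) -> float | None:
    """LV pressure at the downward zero-crossing of aortic valve flow."""
    if beat.q_av is None or not np.any(beat.q_av > 1e-6):
        return None
    open_idx = np.flatnonzero(beat.q_av > 1e-6)
    return float(beat.p_lv[open_idx[-1]])


def beat_metrics(beat: Beat, v0_for_pva: float | None = None) -> BeatMetrics:
    """All scalar metrics of one beat.

    PVA, ME and Art-ca require ``v0_for_pva`` (the volume-axis intercept of
    the end-systolic PV relation fitted over the same occlusion run); without
    it they are left NaN so the fit-then-compute ordering is explicit.
    """
    if np.any(np.diff(beat.t) <= 0):
        raise ValueError("beat time must be strictly increasing")
    edv = float(beat.v_lv[0])
    esv = float(beat.v_lv.min())
    lvedp = float(beat.p_lv[0])
    pes = _pes_at_valve_closure(beat)
    if pes is None:
        pes = float(beat.p_lv[np.argmin(beat.v_lv)])
    pp = float(beat.p_ao.max() - beat.p_ao.min()) if beat.p_ao is not None else float("nan")
    dpdt = float(np.max(np.gradient(beat.p_lv, beat.t)))
    sw = stroke_work(beat)
    m = BeatMetrics(
        EDV=edv, ESV=esv, SV=edv - esv, SW=sw, Pes=pes, LVEDP=lvedp,
        PP=pp, dPdt_max=dpdt, index=beat.index,
        is_steady_state=beat.is_steady_state, is_vco=beat.is_vco,
    )
    if v0_for_pva is not None:
        m.PVA = pv_area(sw, pes, esv, v0_for_pva)
        m.ME = mechanical_efficiency(sw, m.PVA)
    if pes > 0:
        m.Art_ca = dynamic_compliance(m.SV, pes)
    return m


def metrics_frame(metrics: list[BeatMetrics]) -> pd.DataFrame:
    """Per-beat metrics as a DataFrame (the metrics.csv schema)."""
    return pd.DataFrame([m.as_dict() for m in metrics])
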