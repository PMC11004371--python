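"""Linear fits of the four pressure-volume relations over an occlusion run.

Across the declining-preload beat family produced by a vena caval occlusion,
four relations are linear in a healthy ventricle and their slopes index
contractile state and ventricular-vascular coupling:

* ESPVR: Pes = E_es * (ESV - V0) - end-systolic elastance and volume intercept
* PRSW: SW = M_w * (EDV - V_w) - preload recruitable stroke work
* dP/dt_max-EDV: dP/dt_max = dE/dt_max * (EDV - V_d)
* PVA-EDV: PVA = M_PVA * (EDV - V_PVA)

All fits are unweighted ordinary least squares.  The fit order matters: the
ESPVR fit supplies the V0 used to compute each beat's potential-energy
triangle, after which the PVA-EDV relation (and per-beat mechanical
efficiency) become available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import Beat, BeatMetrics, beat_metrics, segment_beats
from .circuit import TimeSeries
from .elastance import pacing_schedule

__all__ = [
    "RelationFit",
    "linear_lsq",
    "fit_espvr",
    "fit_prsw",
    "fit_dpdt_edv",
    "fit_pva_edv",
    "summarize_condition",
    "harvest_vco_beats",
    "analyze_vco_run",
]


@dataclass(frozen=True)
class RelationFit:
    """Slope, volume-axis intercept and diagnostics of one linear PV relation."""

    relation: str  # ESPVR | PRSW | DPDT_EDV | PVA_EDV
    slope: float
    intercept_volume: float  # ml
    r_squared: float
    n_beats: int


def linear_lsq(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a relation fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x is constant")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), min(max(r2, 0.0), 1.0)


def _fit(relation: str, x, y) -> RelationFit:
    slope, intercept, r2 = linear_lsq(x, y)
    if slope == 0:
        raise ValueError(f"{relation}: zero slope, volume intercept undefined")
    return RelationFit(relation, slope, -intercept / slope, r2, len(np.asarray(x)))


def fit_espvr(beats: list[BeatMetrics]) -> RelationFit:
    """End-systolic PV relation: Pes regressed on ESV."""
    return _fit("ESPVR", [b.ESV for b in beats], [b.Pes for b in beats])


def fit_prsw(beats: list[BeatMetrics]) -> RelationFit:
    """Preload recruitable stroke work: SW regressed on EDV."""
    return _fit("PRSW", [b.EDV for b in beats], [b.SW for b in beats])


def fit_dpdt_edv(beats: list[BeatMetrics]) -> RelationFit:
    """Peak dP/dt regressed on EDV; the slope approximates dE/dt_max."""
    return _fit("DPDT_EDV", [b.EDV for b in beats], [b.dPdt_max for b in beats])


def fit_pva_edv(beats: list[BeatMetrics]) -> RelationFit:
    """Pressure-volume area regressed on EDV (energy demand per unit preload)."""
    pva = [b.PVA for b in beats]
    if np.any(np.isnan(pva)):
        raise ValueError("PVA not yet computed; fit ESPVR first to obtain V0")
    return _fit("PVA_EDV", [b.EDV for b in beats], pva)


def summarize_condition(steady: BeatMetrics,
                        fits: dict[str, RelationFit | None]) -> dict:
    """One study-table row: steady-state metrics plus the four slopes.

    Missing fits are flagged (None slope) rather than raising, so a study
    loop can keep going when one condition fails.
    """
    def _slope(key: str):
        f = fits.get(key)
        return f.slope if f is not None else None

    missing = [k for k in ("ESPVR", "PRSW", "DPDT_EDV", "PVA_EDV")
               if fits.get(k) is None]
    return {
        "EDV_ml": steady.EDV, "ESV_ml": steady.ESV, "SV_ml": steady.SV,
        "SW_mmHg_ml": steady.SW, "Pes_mmHg": steady.Pes,
        "LVEDP_mmHg": steady.LVEDP, "dPdtmax_mmHg_s": steady.dPdt_max,
        "PP_mmHg": steady.PP, "ArtCa_ml_mmHg": steady.Art_ca,
        "ESPVR": _slope("ESPVR"), "dPdt_EDV": _slope("DPDT_EDV"),
        "PRSW": _slope("PRSW"), "EDV_PVA": _slope("PVA_EDV"),
        "ME_pct": steady.ME,
        "error": f"missing fits: {', '.join(missing)}" if missing else None,
    }


def harvest_vco_beats(ts: TimeSeries, heart_rate: float,
                      edv_fall_fraction: float = 0.4,
                      include_first_vco: bool = True) -> tuple[Beat, list[Beat]]:
    """Select the steady reference beat and the occlusion family.

    Returns the last steady-state beat and the run of beats from that beat
    (the first beat of the occlusion, by the steady-state-sampling
    convention) until end-diastolic volume has fallen by ``edv_fall_fraction``
    of its steady value, or the trace ends.
    """
    schedule = pacing_schedule(heart_rate, float(ts.time[-1] - ts.time[0]))
    beats = segment_beats(ts, schedule)
    steady_beats = [b for b in beats if b.is_steady_state]
    if not steady_beats:
        raise ValueError("no steady-state beat before the occlusion")
    steady = steady_beats[-1]
    edv0 = float(steady.v_lv[0])
    family = [steady] if include_first_vco else []
    for b in beats:
        if not b.is_vco:
            continue
        if float(b.v_lv[0]) < (1.0 - edv_fall_fraction) * edv0:
            break
        family.append(b)
    return steady, family


def analyze_vco_run(ts: TimeSeries, heart_rate: float,
                    edv_fall_fraction: float = 0.4,
                    include_first_vco: bool = True) -> dict:
    """Full analysis of one occlusion run: metrics, fits, study-table row."""
    steady, family = harvest_vco_beats(ts, heart_rate, edv_fall_fraction,
                                       include_first_vco)
    raw = [beat_metrics(b) for b in family]
    espvr = fit_espvr(raw)
    v0 = espvr.intercept_volume
    metrics = [beat_metrics(b, v0_for_pva=v0) for b in family]
    fits = {
        "ESPVR": espvr,
        "PRSW": fit_prsw(metrics),
        "DPDT_EDV": fit_dpdt_edv(metrics),
        "PVA_EDV": fit_pva_edv(metrics),
    }
    steady_m = beat_metrics(steady, v0_for_pva=v0)
    row = summarize_condition(steady_m, fits)
    row["n_beats"] = len(metrics)
    row["espvr_v0_ml"] = v0
    row["espvr_r2"] = espvr.r_squared
    return row
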