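"""Deterministic synthetic beats and occlusion families with known structure.

These generators stand in for raw simulator output so the analysis layer
(beat metrics and relation fits) can be tested against exact ground truth:
an analytic rectangular PV loop with known area, an occlusion beat family
lying exactly on four specified linear relations (plus optional seeded
Gaussian noise), and a single-chamber ejection into a two-element Windkessel
afterload for integration tests of the elastance identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .beats import Beat, BeatMetrics
from .config import ChamberParams
from .elastance import PacingSchedule, chamber_elastance

__all__ = [
    "FixtureSpec",
    "make_rect_loop",
    "make_vco_family",
    "make_elastance_beat",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Ground-truth linear structure of a synthetic occlusion family."""

    espvr_slope: float = 1.8  # mmHg/ml
    v0: float = 15.0  # ml
    prsw_slope: float = 75.0  # mmHg
    vw: float = 20.0  # ml
    pva_slope: float = 92.0  # mmHg
    v_pva: float = 25.0  # ml
    dpdt_slope: float = 17.0  # mmHg/s/ml
    v_dpdt: float = 15.0  # ml
    edv_start: float = 120.0  # ml
    edv_step: float = 3.0  # ml per beat
    n_beats: int = 12
    noise_sd_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beats < 3:
            raise ValueError("n_beats must be >= 3")
        if self.edv_step <= 0:
            raise ValueError("edv_step must be > 0")
        if not (0.0 <= self.noise_sd_fraction <= 0.1):
            raise ValueError("noise_sd_fraction must lie in [0, 0.1]")


def make_rect_loop(v_low: float, v_high: float, p_low: float, p_high: float,
                   n_samples: int = 400) -> Beat:
    """Closed rectangular (V, P) loop with analytic area.

    Traversed counterclockwise from end-diastole (v_high, p_low):
    isovolumic pressurisation, ejection at p_high, isovolumic relaxation,
    refilling at p_low.  True stroke work = (p_high-p_low)*(v_high-v_low).
    """
    if not (v_high > v_low and p_high > p_low):
        raise ValueError("degenerate rectangle: require v_high > v_low and p_high > p_low")
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    n = n_samples // 4
    m = n_samples - 3 * n
    v = np.concatenate([
        np.full(n, v_high),                      # isovolumic contraction
        np.linspace(v_high, v_low, n, endpoint=False),  # ejection
        np.full(n, v_low),                       # isovolumic relaxation
        np.linspace(v_low, v_high, m, endpoint=False),  # filling
    ])
    p = np.concatenate([
        np.linspace(p_low, p_high, n, endpoint=False),
        np.full(n, p_high),
        np.linspace(p_high, p_low, n, endpoint=False),
        np.full(m, p_low),
    ])
    t = np.linspace(0.0, 0.75, n_samples, endpoint=False)
    return Beat(index=0, t=t, p_lv=p, v_lv=v, is_steady_state=True)


def make_vco_family(spec: FixtureSpec) -> list[BeatMetrics]:
    """Beat metrics descending in EDV, generated from the four specified lines.

    Pes, SW, dP/dt_max and PVA follow their linear relations exactly at zero
    noise; ESV is derived consistently from the Suga decomposition
    PVA - SW = Pes * (ESV - V0) / 2 together with the end-systolic relation,
    so the recovered ESPVR equals the specified slope.  Noise is seeded,
    additive Gaussian with SD = noise_sd_fraction * |value|.
    """
    rng = np.random.default_rng(spec.seed)

    def jitter(value: float) -> float:
        if spec.noise_sd_fraction == 0.0:
            return value
        return value + abs(value) * spec.noise_sd_fraction * rng.standard_normal()

    out = []
    for i in range(spec.n_beats):
        edv = spec.edv_start - i * spec.edv_step
        sw = spec.prsw_slope * (edv - spec.vw)
        pva = spec.pva_slope * (edv - spec.v_pva)
        dpdt = spec.dpdt_slope * (edv - spec.v_dpdt)
        pe = pva - sw
        if pe < 0 or sw <= 0:
            raise ValueError(f"inconsistent spec: negative energy at EDV={edv:.1f} ml")
        esv = spec.v0 + np.sqrt(2.0 * pe / spec.espvr_slope)
        pes = spec.espvr_slope * (esv - spec.v0)
        if esv >= edv:
            raise ValueError(f"inconsistent spec: ESV {esv:.1f} >= EDV {edv:.1f} ml")
        pes_j, sw_j, pva_j, dpdt_j = (jitter(pes), jitter(sw), jitter(pva), jitter(dpdt))
        out.append(BeatMetrics(
            EDV=edv, ESV=esv, SV=edv - esv, SW=sw_j, Pes=pes_j,
            LVEDP=0.05 * edv, PP=pes_j * 0.35, dPdt_max=dpdt_j, PVA=pva_j,
            ME=100.0 * sw_j / pva_j if pva_j > 0 else float("nan"),
            Art_ca=(edv - esv) / pes_j if pes_j > 0 else float("nan"),
            index=i, is_steady_state=(i == 0), is_vco=(i > 0),
        ))
    return out


def make_elastance_beat(e_max: float = 2.0, e_min: float = 0.06, v0: float = 10.0,
                        afterload_r: float = 1.2, afterload_c: float = 1.0,
                        hr: float = 80.0, n_settle_beats: int = 10) -> Beat:
    """One steady beat of an isolated elastance chamber ejecting into an RC load.

    A minimal two-state model: chamber volume and arterial volume.  The
    chamber fills from a constant-pressure venous source through an inflow
    valve and ejects through an outflow valve into a compliance that drains
    through a resistance to zero pressure.  After settling, the end-systolic
    point lies on the line e_max * (V - v0) to within a few percent.
    """
    period = 60.0 / hr
    sf = 0.45
    ch = ChamberParams(e_max, e_min, v0, 0.0, sf)
    schedule = PacingSchedule(hr, np.array([0.0]), period)
    p_fill, r_fill, r_ej = 12.0, 0.06, 0.005

    def rhs(t, y):
        v, va = y
        e_t = float(chamber_elastance(t % period, ch, schedule))
        p = e_t * (v - v0)
        pa = va / afterload_c
        q_in = max(p_fill - p, 0.0) / r_fill
        q_out = max(p - pa, 0.0) / r_ej
        return [q_in - q_out, q_out - pa / afterload_r]

    y0 = [v0 + p_fill / e_min * 0.8, afterload_c * 70.0]
    t_end = n_settle_beats * period
    t_eval = np.arange(int((period) * 1000)) / 1000.0 + (t_end - period)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
                    max_step=1e-3, rtol=1e-7, atol=1e-7)
    if not sol.success:
        raise RuntimeError(f"mini-model solver failed: {sol.message}")
    v = sol.y[0]
    e_t = np.asarray(chamber_elastance(np.mod(sol.t, period), ch, schedule))
    p = e_t * (v - v0)
    pa = sol.y[1] / afterload_c
    q_av = np.maximum(p - pa, 0.0) / r_ej
    t = sol.t - sol.t[0]
    return Beat(index=0, t=t, p_lv=p, v_lv=v, p_ao=pa, q_av=q_av,
                is_steady_state=True)
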