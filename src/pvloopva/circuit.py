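"""Closed-loop lumped-parameter hemodynamic network and its ODE integration.

The state vector holds the blood volume of every chamber and compartment
(15 entries); each derivative is inflow minus outflow, so total blood volume
is conserved exactly by construction.  Valves are ideal diodes with a small
open resistance and no inertance.  The stiff-capable LSODA integrator is used
with a 1 ms step ceiling, and trajectories are resampled at 1 kHz so that
derivative-based metrics (dP/dt_max) are well resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import (
    CHAMBER_NAMES,
    COMPARTMENT_NAMES,
    DISTAL_COMPARTMENTS,
    ModelConfig,
)
from . import elastance as _elastance
from .elastance import PacingSchedule, chamber_elastance, pacing_schedule

__all__ = [
    "ModelState",
    "TimeSeries",
    "valve_flow",
    "state_derivative",
    "simulate",
    "run_to_steady_state",
    "total_blood_volume",
    "initial_state",
    "SteadyStateInfo",
]

N_STATE = len(CHAMBER_NAMES) + len(COMPARTMENT_NAMES)


@dataclass(frozen=True)
class ModelState:
    """Instantaneous volumes (ml) of the four chambers and eleven compartments."""

    chamber_volumes: dict[str, float]
    compartment_volumes: dict[str, float]
    time: float = 0.0

    def to_vector(self) -> np.ndarray:
        y = [self.chamber_volumes[n] for n in CHAMBER_NAMES]
        y += [self.compartment_volumes[n] for n in COMPARTMENT_NAMES]
        return np.asarray(y, dtype=float)

    @classmethod
    def from_vector(cls, y: Sequence[float], time: float = 0.0) -> "ModelState":
        y = np.asarray(y, dtype=float)
        nc = len(CHAMBER_NAMES)
        return cls(
            chamber_volumes=dict(zip(CHAMBER_NAMES, y[:nc])),
            compartment_volumes=dict(zip(COMPARTMENT_NAMES, y[nc:])),
            time=time,
        )


@dataclass
class SteadyStateInfo:
    converged: bool
    criterion: str
    n_beats: int
    duration: float


@dataclass
class TimeSeries:
    """Sampled trajectory of the quantities the analysis layer consumes."""

    time: np.ndarray  # s
    p_lv: np.ndarray  # mmHg
    v_lv: np.ndarray  # ml
    p_ao: np.ndarray  # mmHg (aortic arch)
    q_av: np.ndarray  # ml/s aortic valve flow
    q_mv: np.ndarray  # ml/s mitral valve flow
    compartment_pressures: dict[str, np.ndarray] = field(default_factory=dict)
    vco_start: float | None = None
    final_state: ModelState | None = None
    steady_state: SteadyStateInfo | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("p_lv", "v_lv", "p_ao", "q_av", "q_mv"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array length mismatch for {name}")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "time_s": self.time,
            "p_lv_mmHg": self.p_lv,
            "v_lv_ml": self.v_lv,
            "p_ao_mmHg": self.p_ao,
            "q_av_ml_s": self.q_av,
            "q_mv_ml_s": self.q_mv,
        }
        for name, arr in self.compartment_pressures.items():
            cols[f"p_{name}_mmHg"] = arr
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeSeries":
        required = ["time_s", "p_lv_mmHg", "v_lv_ml"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        n = len(df)
        zeros = np.zeros(n)
        comp = {}
        for col in df.columns:
            if col.startswith("p_") and col.endswith("_mmHg") and col not in (
                    "p_lv_mmHg", "p_ao_mmHg"):
                comp[col[2:-5]] = df[col].to_numpy(float)
        return cls(
            time=df["time_s"].to_numpy(float),
            p_lv=df["p_lv_mmHg"].to_numpy(float),
            v_lv=df["v_lv_ml"].to_numpy(float),
            p_ao=df["p_ao_mmHg"].to_numpy(float) if "p_ao_mmHg" in df else zeros.copy(),
            q_av=df["q_av_ml_s"].to_numpy(float) if "q_av_ml_s" in df else zeros.copy(),
            q_mv=df["q_mv_ml_s"].to_numpy(float) if "q_mv_ml_s" in df else zeros.copy(),
            compartment_pressures=comp,
        )

    @classmethod
    def read_csv(cls, path) -> "TimeSeries":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def concatenate(cls, parts: Sequence["TimeSeries"]) -> "TimeSeries":
        time = np.concatenate([p.time for p in parts])
        # segments share their boundary sample; keep the first occurrence
        keep = np.diff(time, prepend=-np.inf) > 0
        keys = set(parts[0].compartment_pressures)
        comp = {k: np.concatenate([p.compartment_pressures[k] for p in parts])[keep]
                for k in keys}
        out = cls(
            time=time[keep],
            p_lv=np.concatenate([p.p_lv for p in parts])[keep],
            v_lv=np.concatenate([p.v_lv for p in parts])[keep],
            p_ao=np.concatenate([p.p_ao for p in parts])[keep],
            q_av=np.concatenate([p.q_av for p in parts])[keep],
            q_mv=np.concatenate([p.q_mv for p in parts])[keep],
            compartment_pressures=comp,
            final_state=parts[-1].final_state,
        )
        for p in parts:
            if p.vco_start is not None:
                out.vco_start = p.vco_start
            if p.steady_state is not None:
                out.steady_state = p.steady_state
        return out


def valve_flow(p_upstream: float, p_downstream: float, r_open: float) -> float:
    """Ideal-diode valve: Ohmic when the gradient is forward, zero otherwise."""
    if r_open <= 0:
        raise ValueError("r_open must be > 0")
    dp = p_upstream - p_downstream
    return dp / r_open if dp > 0 else 0.0


class _Network:
    """Config compiled into flat scalars with a fast right-hand side."""

    def __init__(self, config: ModelConfig,
                 tvn_resistance: Callable[[float], float] | None = None):
        self.config = config
        self.period = config.beat_period
        self.floor = config.pressure_floor
        # chamber parameters in state order, with the force-frequency gain on
        # ventricular E_max
        gain = 1.0 + config.force_frequency_slope * (
            (config.heart_rate - config.reference_hr) / config.reference_hr)
        self.chamber_params = []
        for name in CHAMBER_NAMES:
            ch = config.chambers[name]
            e_max = ch.E_max * gain if name.endswith("ventricle") else ch.E_max
            self.chamber_params.append(
                (e_max, ch.E_min, ch.V0_chamber,
                 ch.activation_onset_fraction, ch.systole_fraction))
        comp = {c.name: c for c in config.compartments}
        self.C = np.array([comp[n].compliance for n in COMPARTMENT_NAMES])
        self.Vu = np.array([comp[n].unstressed_volume for n in COMPARTMENT_NAMES])
        self.r_out = {n: comp[n].resistance_out for n in COMPARTMENT_NAMES}
        self.r_in = {n: comp[n].resistance_in for n in DISTAL_COMPARTMENTS}
        self.r_av = config.r_aortic_valve
        self.r_mv = config.r_mitral_valve
        self.r_pv = config.r_pulmonic_valve
        self.r_tv = config.r_tricuspid_valve
        self.tvn_resistance = tvn_resistance  # VCO override of thoracic-vein outflow
        self._rise = _elastance.RISE_EXPONENT
        self._relax = _elastance.RELAX_FRACTION
        self.idx = {n: i for i, n in enumerate(
            list(CHAMBER_NAMES) + list(COMPARTMENT_NAMES))}

    # -- elastance (scalar, hot path) --------------------------------------

    def _elastance(self, t: float, params) -> float:
        e_max, e_min, _v0, onset, sf = params
        u = (t / self.period - onset) % 1.0
        rf = self._relax * sf
        if u < sf:
            a = (0.5 * (1.0 - math.cos(math.pi * u / sf))) ** self._rise
        elif u < sf + rf:
            a = 0.5 * (1.0 + math.cos(math.pi * (u - sf) / rf))
        else:
            a = 0.0
        return e_min + (e_max - e_min) * a

    def chamber_pressure(self, t: float, v: float, params) -> float:
        p = self._elastance(t, params) * (v - params[2])
        return p if p > self.floor else self.floor

    # -- flows and derivative ----------------------------------------------

    def flows(self, t: float, y) -> dict[str, float]:
        idx = self.idx
        p_la = self.chamber_pressure(t, y[idx["left_atrium"]], self.chamber_params[0])
        p_lv = self.chamber_pressure(t, y[idx["left_ventricle"]], self.chamber_params[1])
        p_ra = self.chamber_pressure(t, y[idx["right_atrium"]], self.chamber_params[2])
        p_rv = self.chamber_pressure(t, y[idx["right_ventricle"]], self.chamber_params[3])
        pc = (y[4:] - self.Vu) / self.C
        p = dict(zip(COMPARTMENT_NAMES, pc))
        r_tvn = self.r_out["thoracic_vein"]
        if self.tvn_resistance is not None:
            r_tvn = self.tvn_resistance(t)
        q = {
            "mitral": max(p_la - p_lv, 0.0) / self.r_mv,
            "aortic": max(p_lv - p["aortic_arch"], 0.0) / self.r_av,
            "prox": (p["aortic_arch"] - p["systemic_artery"]) / self.r_out["aortic_arch"],
            "svn": (p["systemic_vein"] - p["thoracic_vein"]) / self.r_out["systemic_vein"],
            "tvn": (p["thoracic_vein"] - p_ra) / r_tvn,
            "tricuspid": max(p_ra - p_rv, 0.0) / self.r_tv,
            "pulmonic": max(p_rv - p["pulmonary_artery"], 0.0) / self.r_pv,
            "pa": (p["pulmonary_artery"] - p["pulmonary_vein"]) / self.r_out["pulmonary_artery"],
            "pv": (p["pulmonary_vein"] - p_la) / self.r_out["pulmonary_vein"],
        }
        for name in DISTAL_COMPARTMENTS:
            q[f"in_{name}"] = (p["systemic_artery"] - p[name]) / self.r_in[name]
            q[f"out_{name}"] = (p[name] - p["systemic_vein"]) / self.r_out[name]
        q["_p_la"], q["_p_lv"], q["_p_ra"], q["_p_rv"] = p_la, p_lv, p_ra, p_rv
        return q

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            bad = int(np.argmax(~np.isfinite(y)))
            name = (list(CHAMBER_NAMES) + list(COMPARTMENT_NAMES))[bad]
            raise FloatingPointError(
                f"non-finite state component {name!r} at t={t:.4f} s (solver divergence)")
        q = self.flows(t, y)
        dist_in = sum(q[f"in_{n}"] for n in DISTAL_COMPARTMENTS)
        dist_out = sum(q[f"out_{n}"] for n in DISTAL_COMPARTMENTS)
        dy = np.empty(N_STATE)
        dy[0] = q["pv"] - q["mitral"]          # left atrium
        dy[1] = q["mitral"] - q["aortic"]      # left ventricle
        dy[2] = q["tvn"] - q["tricuspid"]      # right atrium
        dy[3] = q["tricuspid"] - q["pulmonic"] # right ventricle
        dy[4] = q["aortic"] - q["prox"]        # aortic arch
        dy[5] = q["prox"] - dist_in            # systemic artery
        for i, n in enumerate(DISTAL_COMPARTMENTS):
            dy[6 + i] = q[f"in_{n}"] - q[f"out_{n}"]
        dy[11] = dist_out - q["svn"]           # systemic vein
        dy[12] = q["svn"] - q["tvn"]           # thoracic vein
        dy[13] = q["pulmonic"] - q["pa"]       # pulmonary artery
        dy[14] = q["pa"] - q["pv"]             # pulmonary vein
        return dy

    def sample_outputs(self, t: np.ndarray, y: np.ndarray) -> TimeSeries:
        """Vectorised recomputation of pressures/flows on the sample grid."""
        schedule = PacingSchedule(self.config.heart_rate,
                                  np.array([0.0]), self.period)
        gain_params = dict(zip(CHAMBER_NAMES, self.chamber_params))
        from .config import ChamberParams  # local to avoid cycle at import time

        def _pressure(name: str, v: np.ndarray) -> np.ndarray:
            e_max, e_min, v0, onset, sf = gain_params[name]
            ch = ChamberParams(e_max, e_min, v0, onset, sf)
            e_t = chamber_elastance(t, ch, schedule)
            return np.maximum(e_t * (v - v0), self.floor)

        p_lv = _pressure("left_ventricle", y[1])
        p_la = _pressure("left_atrium", y[0])
        pc = {n: (y[4 + i] - self.Vu[i]) / self.C[i]
              for i, n in enumerate(COMPARTMENT_NAMES)}
        q_av = np.maximum(p_lv - pc["aortic_arch"], 0.0) / self.r_av
        q_mv = np.maximum(p_la - p_lv, 0.0) / self.r_mv
        return TimeSeries(
            time=t.copy(), p_lv=p_lv, v_lv=y[1].copy(), p_ao=pc["aortic_arch"],
            q_av=q_av, q_mv=q_mv, compartment_pressures=pc,
            final_state=ModelState.from_vector(y[:, -1], time=float(t[-1])),
        )


def state_derivative(state: ModelState, t: float, config: ModelConfig) -> np.ndarray:
    """Volume rates (ml/s) for every chamber and compartment; sums to zero."""
    return _Network(config).rhs(t, state.to_vector())


def total_blood_volume(state: ModelState) -> float:
    """Sum of all chamber and compartment volumes (ml)."""
    return float(sum(state.chamber_volumes.values())
                 + sum(state.compartment_volumes.values()))


def initial_state(config: ModelConfig) -> ModelState:
    """Physiologically plausible starting volumes summing to the configured total.

    Arterial compartments are charged to ~90 mmHg, veins to a few mmHg and
    the chambers to diastolic volumes; the residual goes to the systemic
    vein, the largest reservoir, so total volume matches exactly.
    """
    guess_p = {
        "aortic_arch": 90.0, "systemic_artery": 88.0,
        "coronary": 85.0, "cerebral": 85.0, "skeletal_muscle": 85.0,
        "splanchnic": 85.0, "extrasplanchnic": 85.0,
        "systemic_vein": 6.0, "thoracic_vein": 5.0,
        "pulmonary_artery": 15.0, "pulmonary_vein": 8.0,
    }
    comp_v = {c.name: c.unstressed_volume + c.compliance * guess_p[c.name]
              for c in config.compartments}
    ch = config.chambers
    cham_v = {
        "left_ventricle": ch["left_ventricle"].V0_chamber + 105.0,
        "left_atrium": ch["left_atrium"].V0_chamber + 45.0,
        "right_ventricle": ch["right_ventricle"].V0_chamber + 110.0,
        "right_atrium": ch["right_atrium"].V0_chamber + 45.0,
    }
    residual = config.total_blood_volume - sum(comp_v.values()) - sum(cham_v.values())
    comp_v["systemic_vein"] += residual
    if comp_v["systemic_vein"] < 0:
        raise ValueError("total_blood_volume too small for the configured unstressed volumes")
    return ModelState(chamber_volumes=cham_v, compartment_volumes=comp_v, time=0.0)


def simulate(config: ModelConfig, duration: float,
             initial: ModelState | None = None,
             tvn_resistance: Callable[[float], float] | None = None,
             t0: float = 0.0) -> TimeSeries:
    """Integrate the closed loop for ``duration`` seconds from ``initial``.

    The returned trajectory is sampled at the configured analysis rate
    (default 1 kHz).  Pacing is phase-locked to absolute time: beat onsets sit
    at integer multiples of the period, so restarts preserve the phase.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if initial is None:
        initial = initial_state(config)
    y0 = initial.to_vector()
    if np.any(y0 < 0) or not np.all(np.isfinite(y0)):
        raise ValueError("initial volumes must be finite and non-negative")
    net = _Network(config, tvn_resistance=tvn_resistance)
    dt = 1.0 / config.solver.sample_rate
    n = int(np.floor(duration / dt + 1e-9))
    t_eval = t0 + np.arange(n + 1) * dt
    t_end = t0 + duration
    if t_end - t_eval[-1] > 1e-9:
        t_eval = np.append(t_eval, t_end)  # keep the exact segment endpoint
    else:
        t_eval[-1] = t_end
    sol = solve_ivp(
        net.rhs, (t0, t0 + duration), y0, method="LSODA", t_eval=t_eval,
        max_step=config.solver.max_step, rtol=config.solver.rel_tol,
        atol=config.solver.abs_tol)
    if not sol.success:
        raise RuntimeError(f"solver failed at t={sol.t[-1] if sol.t.size else t0:.4f} s: "
                           f"{sol.message}")
    return net.sample_outputs(sol.t, sol.y)


def _beat_metrics_for_convergence(ts: TimeSeries, period: float) -> np.ndarray:
    """(EDV, ESV, mean AoP) per complete beat in the chunk, keyed to onsets."""
    t0 = ts.time[0]
    n_beats = int(np.floor((ts.time[-1] - t0) / period + 1e-9))
    rows = []
    for k in range(n_beats):
        sel = (ts.time >= t0 + k * period - 1e-9) & (ts.time < t0 + (k + 1) * period - 1e-9)
        if sel.sum() < 10:
            continue
        rows.append((ts.v_lv[sel][0], ts.v_lv[sel].min(), ts.p_ao[sel].mean()))
    return np.asarray(rows)


def run_to_steady_state(config: ModelConfig,
                        initial: ModelState | None = None,
                        max_duration: float = 180.0,
                        tolerance: float = 0.005,
                        window_beats: int = 5) -> tuple[TimeSeries, ModelState]:
    """Integrate until beat metrics settle, or ``max_duration`` elapses.

    Convergence fires when EDV, ESV and mean aortic pressure each vary by
    less than ``tolerance`` (relative peak-to-peak) across ``window_beats``
    consecutive beats.  Non-convergence is recorded on the result, not fatal.
    """
    period = config.beat_period
    if initial is None:
        initial = initial_state(config)
    chunks: list[TimeSeries] = []
    state = initial
    elapsed = 0.0
    history: list[tuple[float, float, float]] = []
    converged, criterion, n_total = False, "", 0
    while elapsed < max_duration - 1e-9:
        n_beats = min(window_beats, int(math.ceil((max_duration - elapsed) / period)))
        ts = simulate(config, n_beats * period, initial=state, t0=elapsed)
        chunks.append(ts)
        state = ts.final_state
        elapsed += n_beats * period
        m = _beat_metrics_for_convergence(ts, period)
        history.extend(map(tuple, m))
        n_total = len(history)
        if len(history) >= window_beats:
            win = np.asarray(history[-window_beats:])
            rel = (win.max(axis=0) - win.min(axis=0)) / np.abs(win.mean(axis=0))
            if np.all(rel < tolerance):
                converged = True
                criterion = (f"beat-to-beat variation of EDV/ESV/mean AoP < "
                             f"{tolerance:.1%} over {window_beats} beats")
                break
    if not converged:
        criterion = f"maximum duration {max_duration:.0f} s reached without convergence"
    out = TimeSeries.concatenate(chunks)
    out.steady_state = SteadyStateInfo(converged, criterion, n_total, elapsed)
    return out, state
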