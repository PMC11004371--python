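"""Experiment drivers: graded arterial stiffening, the simulated vena caval
occlusion (VCO), and the two study phases.

The five compliance/resistance settings span the vascular-aging spectrum from
the normal adult aorta (C_A = 0.70 ml/mmHg, R_T = 1.28 mmHg*s/ml) to a rigid
("stiff") conduit (C_A = 0.19, R_T = 3.66).  Stiffening is applied by scaling
every arterial compliance by a common factor and every arterial resistance by
a common factor, so the proximal/distal split of the normal configuration is
preserved while the equivalent C_A and R_T hit the target pair exactly.

The VCO ramps up the outflow resistance of the thoracic veins (the venous
return path into the right atrium, distal to the systemic-vein pool), which
starves the right heart of preload and walks the left ventricle down the
pressure-volume plane beat by beat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .circuit import TimeSeries, run_to_steady_state, simulate
from .config import ARTERIAL_COMPARTMENTS, ModelConfig, default_config

__all__ = [
    "ComplianceSetting",
    "VcoParams",
    "COMPLIANCE_LEVELS",
    "compliance_setting",
    "apply_vascular_scaling",
    "vco_resistance",
    "run_vco_experiment",
    "run_phase1",
    "run_phase2",
]


@dataclass(frozen=True)
class ComplianceSetting:
    """One point on the vascular-aging spectrum: equivalent C_A and R_T."""

    level: str
    C_A: float  # ml/mmHg
    R_T: float  # mmHg*s/ml


#: The five packaged settings: normal, 10/20/40 percent compliance reductions,
#: and the stiff conduit.
COMPLIANCE_LEVELS: dict[str, ComplianceSetting] = {
    s.level: s for s in (
        ComplianceSetting("normal", 0.70, 1.28),
        ComplianceSetting("90pct", 0.63, 1.41),
        ComplianceSetting("80pct", 0.56, 1.54),
        ComplianceSetting("60pct", 0.42, 1.805),
        ComplianceSetting("stiff", 0.19, 3.66),
    )
}


def compliance_setting(level: str) -> ComplianceSetting:
    """Look up one of the five packaged compliance/resistance pairs."""
    try:
        return COMPLIANCE_LEVELS[level]
    except KeyError:
        raise ValueError(
            f"unknown compliance level {level!r}; valid levels: "
            f"{', '.join(COMPLIANCE_LEVELS)}") from None


@dataclass(frozen=True)
class VcoParams:
    """Schedule of the venous-return occlusion.

    The thoracic-vein outflow resistance rises from baseline to
    ``resistance_multiplier`` x baseline over ``ramp_duration`` seconds,
    geometrically for the exponential profile, linearly otherwise, and stays
    there.  A multiplier >= 10 guarantees a falling preload; smaller values
    (down to the degenerate 1, a null occlusion) are allowed with a warning.
    """

    start_time: float = 0.0  # s, relative to the trajectory clock
    ramp_duration: float = 8.0  # s
    resistance_multiplier: float = 100.0
    profile: str = "exponential"

    def __post_init__(self) -> None:
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be > 0")
        if self.resistance_multiplier < 1:
            raise ValueError("resistance_multiplier must be >= 1")
        if self.resistance_multiplier < 10:
            warnings.warn("resistance_multiplier < 10 may not produce a falling preload",
                          stacklevel=3)
        if self.profile not in ("exponential", "linear"):
            raise ValueError("profile must be 'exponential' or 'linear'")


def vco_resistance(t: float, params: VcoParams, baseline_r: float) -> float:
    """Thoracic-vein outflow resistance at time ``t`` under the occlusion ramp."""
    if t < params.start_time:
        return baseline_r
    x = min((t - params.start_time) / params.ramp_duration, 1.0)
    if params.profile == "exponential":
        return baseline_r * params.resistance_multiplier ** x
    return baseline_r * (1.0 + (params.resistance_multiplier - 1.0) * x)


def apply_vascular_scaling(config: ModelConfig, setting: ComplianceSetting) -> ModelConfig:
    """Retarget the arterial tree to a new equivalent (C_A, R_T) pair.

    Every arterial compliance is multiplied by ``setting.C_A`` over the
    current equivalent compliance, and every arterial resistance (proximal
    and distal, feed and outflow) by ``setting.R_T`` over the current
    equivalent resistance; the venous and pulmonary sides are untouched.
    The operation is exact, idempotent and order-independent.
    """
    c_now = config.arterial_compliance
    r_now = config.total_peripheral_resistance
    if c_now <= 0:
        raise ValueError("current equivalent compliance is singular")
    fc = setting.C_A / c_now
    fr = setting.R_T / r_now
    comps = []
    for c in config.compartments:
        if c.name in ARTERIAL_COMPARTMENTS:
            c = replace(c, compliance=c.compliance * fc,
                        resistance_out=c.resistance_out * fr,
                        resistance_in=c.resistance_in * fr)
        comps.append(c)
    return replace(config, compartments=tuple(comps))


def run_vco_experiment(setting: ComplianceSetting,
                       heart_rate: float = 80.0,
                       vco: VcoParams | None = None,
                       config: ModelConfig | None = None,
                       vco_window: float = 12.0,
                       max_settle: float = 180.0) -> TimeSeries:
    """Settle the loop at a compliance setting, then occlude venous return.

    Returns the steady-state tail and the occlusion window concatenated, with
    ``vco_start`` marking the boundary.  Beats before the marker are steady;
    beats after it form the declining-preload family the relation fits use.
    """
    if config is None:
        config = default_config(heart_rate)
    elif config.heart_rate != heart_rate:
        config = config.with_heart_rate(heart_rate)
    config = apply_vascular_scaling(config, setting)
    if vco is None:
        vco = VcoParams()
    steady, state = run_to_steady_state(config, max_duration=max_settle)
    t_start = steady.time[-1]
    baseline_r = config.compartment("thoracic_vein").resistance_out
    sched = replace(vco, start_time=t_start) if vco.start_time == 0.0 else vco
    occluded = simulate(config, vco_window, initial=state, t0=t_start,
                        tvn_resistance=lambda t: vco_resistance(t, sched, baseline_r))
    out = TimeSeries.concatenate([steady, occluded])
    out.vco_start = t_start
    out.steady_state = steady.steady_state
    return out


def _analyze_condition(setting: ComplianceSetting, heart_rate: float,
                       vco: VcoParams | None, **kwargs) -> dict:
    # deferred import: the analysis layer is independent of the simulator
    from .relations import analyze_vco_run
    ts = run_vco_experiment(setting, heart_rate, vco=vco, **kwargs)
    row = analyze_vco_run(ts, heart_rate)
    row.update(level=setting.level, heart_rate=heart_rate,
               C_A=setting.C_A, R_T=setting.R_T,
               converged=bool(ts.steady_state and ts.steady_state.converged))
    return row


_TABLE_COLUMNS = [
    "level", "heart_rate", "C_A", "R_T",
    "EDV_ml", "ESV_ml", "SV_ml", "SW_mmHg_ml", "Pes_mmHg", "LVEDP_mmHg",
    "dPdtmax_mmHg_s", "PP_mmHg", "ArtCa_ml_mmHg",
    "ESPVR", "dPdt_EDV", "PRSW", "EDV_PVA", "ME_pct",
    "converged", "error",
]


def _study_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col in _TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = None
    return df[_TABLE_COLUMNS]


def run_phase1(vco: VcoParams | None = None, **kwargs) -> pd.DataFrame:
    """Phase I: all five compliance settings at 80 bpm, one row per setting."""
    rows = []
    for level in COMPLIANCE_LEVELS:
        try:
            rows.append(_analyze_condition(compliance_setting(level), 80.0, vco, **kwargs))
        except Exception as exc:  # flag the row, keep going
            rows.append({"level": level, "heart_rate": 80.0, "error": str(exc)})
    return _study_table(rows)


def run_phase2(vco: VcoParams | None = None, **kwargs) -> pd.DataFrame:
    """Phase II: normal and stiff settings at 60, 100 and 140 bpm (6 rows)."""
    rows = []
    for level in ("normal", "stiff"):
        for hr in (60.0, 100.0, 140.0):
            try:
                rows.append(_analyze_condition(compliance_setting(level), hr, vco, **kwargs))
            except Exception as exc:
                rows.append({"level": level, "heart_rate": hr, "error": str(exc)})
    return _study_table(rows)
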