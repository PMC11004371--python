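"""Model configuration: chamber, vascular-compartment and solver parameters.

The closed loop is built from four time-varying elastance chambers (left and
right atria and ventricles) and eleven vascular compartments: a proximal
aortic-arch Windkessel element, a lumped systemic-artery node, five parallel
distal arterial beds (coronary, cerebral, skeletal muscle, splanchnic,
extrasplanchnic), lumped systemic and thoracic veins, and a two-compartment
pulmonary loop.  Units are mmHg, ml and s throughout; resistances are
mmHg*s/ml and compliances ml/mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "ChamberParams",
    "VascularCompartment",
    "SolverSettings",
    "ModelConfig",
    "default_config",
    "CHAMBER_NAMES",
    "COMPARTMENT_NAMES",
    "ARTERIAL_COMPARTMENTS",
    "DISTAL_COMPARTMENTS",
]

CHAMBER_NAMES = ("left_atrium", "left_ventricle", "right_atrium", "right_ventricle")

COMPARTMENT_NAMES = (
    "aortic_arch",
    "systemic_artery",
    "coronary",
    "cerebral",
    "skeletal_muscle",
    "splanchnic",
    "extrasplanchnic",
    "systemic_vein",
    "thoracic_vein",
    "pulmonary_artery",
    "pulmonary_vein",
)

#: Compartments whose compliances add up to the equivalent arterial compliance C_A.
ARTERIAL_COMPARTMENTS = COMPARTMENT_NAMES[:7]

#: The five parallel distal systemic beds.
DISTAL_COMPARTMENTS = COMPARTMENT_NAMES[2:7]


@dataclass(frozen=True)
class ChamberParams:
    """Time-varying elastance chamber.

    ``E_max``/``E_min`` bound the periodic elastance; ``V0_chamber`` is the
    unstressed volume at which the chamber generates zero pressure.
    ``activation_onset_fraction`` places the start of activation within the
    pacing cycle (atria are phase-advanced so the atrial kick completes at
    ventricular onset) and ``systole_fraction`` is the fraction of the cycle
    over which elastance rises to its peak.
    """

    E_max: float  # mmHg/ml
    E_min: float  # mmHg/ml
    V0_chamber: float  # ml
    activation_onset_fraction: float = 0.0
    systole_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not (self.E_max > self.E_min > 0):
            raise ValueError(
                f"require E_max > E_min > 0, got E_max={self.E_max}, E_min={self.E_min}"
            )
        if not (0.0 <= self.activation_onset_fraction < 1.0):
            raise ValueError("activation_onset_fraction must lie in [0, 1)")
        if not (0.0 < self.systole_fraction < 1.0):
            raise ValueError("systole_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class VascularCompartment:
    """A passive compliance element with an outflow (and optional inflow) resistance.

    Pressure follows P = (V - unstressed_volume) / compliance.  For the five
    distal beds ``resistance_in`` is the small feed resistance from the
    systemic-artery node; for every other compartment the inflow path belongs
    to the upstream element and ``resistance_in`` is unused (0).
    """

    name: str
    compliance: float  # ml/mmHg
    resistance_out: float  # mmHg*s/ml
    unstressed_volume: float = 0.0  # ml
    resistance_in: float = 0.0  # mmHg*s/ml, distal beds only

    def __post_init__(self) -> None:
        if self.name not in COMPARTMENT_NAMES:
            raise ValueError(f"unknown compartment name {self.name!r}")
        if self.compliance <= 0:
            raise ValueError(f"{self.name}: compliance must be > 0")
        if self.resistance_out <= 0:
            raise ValueError(f"{self.name}: resistance_out must be > 0")
        if self.unstressed_volume < 0:
            raise ValueError(f"{self.name}: unstressed_volume must be >= 0")

    def pressure(self, volume: float) -> float:
        return (volume - self.unstressed_volume) / self.compliance


@dataclass(frozen=True)
class SolverSettings:
    max_step: float = 1e-3  # s
    rel_tol: float = 1e-6
    abs_tol: float = 1e-6  # ml
    sample_rate: float = 1000.0  # Hz, analysis resampling

    def __post_init__(self) -> None:
        if self.max_step <= 0 or self.sample_rate <= 0:
            raise ValueError("max_step and sample_rate must be > 0")


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterisation of the closed loop.

    ``force_frequency_slope`` is the linear gain applied to ventricular E_max
    as heart rate departs from ``reference_hr`` (contractility rises with
    rate); the model runs under autonomic blockade, so no reflex loop exists.
    """

    heart_rate: float  # bpm
    total_blood_volume: float  # ml
    chambers: dict[str, ChamberParams]
    compartments: tuple[VascularCompartment, ...]
    r_aortic_valve: float = 0.005
    r_mitral_valve: float = 0.003
    r_pulmonic_valve: float = 0.005
    r_tricuspid_valve: float = 0.003
    force_frequency_slope: float = 0.3
    reference_hr: float = 80.0
    pressure_floor: float = -5.0  # mmHg, chamber pressure clamp under deep occlusion
    autonomic_blockade: bool = True
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        if not (30.0 <= self.heart_rate <= 220.0):
            raise ValueError(f"heart_rate {self.heart_rate} outside [30, 220] bpm")
        if self.total_blood_volume <= 0:
            raise ValueError("total_blood_volume must be > 0")
        missing = set(CHAMBER_NAMES) - set(self.chambers)
        if missing:
            raise ValueError(f"missing chambers: {sorted(missing)}")
        names = [c.name for c in self.compartments]
        if names != list(COMPARTMENT_NAMES):
            raise ValueError(
                "compartments must appear once each, in canonical order "
                f"{COMPARTMENT_NAMES}"
            )
        for v in (self.r_aortic_valve, self.r_mitral_valve,
                  self.r_pulmonic_valve, self.r_tricuspid_valve):
            if v <= 0:
                raise ValueError("valve resistances must be > 0")
        if not self.autonomic_blockade:
            raise ValueError("model only supports autonomic blockade (no reflex loop)")

    # -- derived equivalent quantities -------------------------------------

    def compartment(self, name: str) -> VascularCompartment:
        return self.compartments[COMPARTMENT_NAMES.index(name)]

    @property
    def arterial_compliance(self) -> float:
        """Equivalent arterial compliance C_A (parallel compliances add)."""
        return sum(self.compartment(n).compliance for n in ARTERIAL_COMPARTMENTS)

    @property
    def total_peripheral_resistance(self) -> float:
        """R_T: proximal arch resistance in series with the parallel distal beds."""
        r_prox = (self.compartment("aortic_arch").resistance_out
                  + self.compartment("systemic_artery").resistance_out)
        g = sum(1.0 / (self.compartment(n).resistance_in + self.compartment(n).resistance_out)
                for n in DISTAL_COMPARTMENTS)
        return r_prox + 1.0 / g

    @property
    def beat_period(self) -> float:
        return 60.0 / self.heart_rate

    def with_heart_rate(self, heart_rate: float) -> "ModelConfig":
        """Re-derive the rate-dependent chamber timings at a new pacing rate."""
        chambers = _chamber_defaults(heart_rate,
                                     lv=self.chambers["left_ventricle"],
                                     rv=self.chambers["right_ventricle"],
                                     la=self.chambers["left_atrium"],
                                     ra=self.chambers["right_atrium"])
        return replace(self, heart_rate=heart_rate, chambers=chambers)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "heart_rate": self.heart_rate,
            "total_blood_volume": self.total_blood_volume,
            "chambers": {k: vars(v).copy() for k, v in self.chambers.items()},
            "compartments": [vars(c).copy() for c in self.compartments],
            "valves": {
                "r_aortic_valve": self.r_aortic_valve,
                "r_mitral_valve": self.r_mitral_valve,
                "r_pulmonic_valve": self.r_pulmonic_valve,
                "r_tricuspid_valve": self.r_tricuspid_valve,
            },
            "force_frequency_slope": self.force_frequency_slope,
            "reference_hr": self.reference_hr,
            "pressure_floor": self.pressure_floor,
            "autonomic_blockade": self.autonomic_blockade,
            "solver": vars(self.solver).copy(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        version = d.get("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config schema version {version}")
        valves = d.get("valves", {})
        return cls(
            heart_rate=d["heart_rate"],
            total_blood_volume=d["total_blood_volume"],
            chambers={k: ChamberParams(**v) for k, v in d["chambers"].items()},
            compartments=tuple(VascularCompartment(**c) for c in d["compartments"]),
            force_frequency_slope=d.get("force_frequency_slope", 0.3),
            reference_hr=d.get("reference_hr", 80.0),
            pressure_floor=d.get("pressure_floor", -5.0),
            autonomic_blockade=d.get("autonomic_blockade", True),
            solver=SolverSettings(**d.get("solver", {})),
            **valves,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Default (normal) parameterisation
# ---------------------------------------------------------------------------

#: Systolic duration scales as k*sqrt(60/HR) (Bazett-like); k calibrated so the
#: normal 80 bpm run reproduces ~120 mmHg systolic / ~40 mmHg pulse pressure
#: with C_A = 0.7 ml/mmHg and R_T = 1.28 mmHg*s/ml.  Long ejection narrows the
#: aortic pulse at this low equivalent compliance; the valve-event ordering
#: (MVC -> AVO -> AVC -> MVO) is preserved and systole shortens at high rate.
SYSTOLE_SCALE = 0.54

#: Ceiling on the fraction of the cycle spent contracting (binds above ~100 bpm,
#: where Bazett scaling alone would leave no diastole at all).
SYSTOLE_FRACTION_CAP = 0.62

#: Atrial activation leads ventricular onset by this interval (s), giving the
#: atrial kick that sets a physiologic LV end-diastolic pressure.
ATRIAL_LEAD = 0.16

#: Duration of the atrial contraction (s).
ATRIAL_SYSTOLE = 0.10


def _chamber_defaults(heart_rate: float,
                      lv: ChamberParams | None = None,
                      rv: ChamberParams | None = None,
                      la: ChamberParams | None = None,
                      ra: ChamberParams | None = None) -> dict[str, ChamberParams]:
    period = 60.0 / heart_rate
    t_sys = SYSTOLE_SCALE * math.sqrt(period)
    vf = min(t_sys / period, SYSTOLE_FRACTION_CAP)
    af = min(ATRIAL_SYSTOLE / period, 0.3)
    a_onset = (1.0 - ATRIAL_LEAD / period) % 1.0

    def _v(base: ChamberParams | None, E_max: float, E_min: float, V0: float) -> ChamberParams:
        if base is None:
            return ChamberParams(E_max, E_min, V0, 0.0, vf)
        return replace(base, activation_onset_fraction=0.0, systole_fraction=vf)

    def _a(base: ChamberParams | None, E_max: float, E_min: float, V0: float) -> ChamberParams:
        if base is None:
            return ChamberParams(E_max, E_min, V0, a_onset, af)
        return replace(base, activation_onset_fraction=a_onset, systole_fraction=af)

    return {
        "left_ventricle": _v(lv, 3.00, 0.060, 5.0),
        "right_ventricle": _v(rv, 0.80, 0.035, 10.0),
        "left_atrium": _a(la, 0.28, 0.10, 5.0),
        "right_atrium": _a(ra, 0.22, 0.08, 5.0),
    }


def _compartment_defaults() -> tuple[VascularCompartment, ...]:
    # Compliance split of C_A = 0.70 ml/mmHg between arch, lumped artery and
    # the five distal beds; resistance split of R_T = 1.28 mmHg*s/ml between
    # the proximal path and the parallel distal beds (conductances weighted by
    # typical regional flow fractions).
    # The proximal arch holds most of C_A so the diastolic decay of aortic
    # pressure sees nearly the full Windkessel time constant C_A * R_T; the
    # distal beds are near-rigid pressure nodes, as in the source topology
    # where distal compliances are held constant and small.
    distal_c = {
        "coronary": 0.0024,
        "cerebral": 0.0048,
        "skeletal_muscle": 0.0072,
        "splanchnic": 0.0060,
        "extrasplanchnic": 0.0036,
    }
    flow_fraction = {
        "coronary": 0.05,
        "cerebral": 0.14,
        "skeletal_muscle": 0.17,
        "splanchnic": 0.44,
        "extrasplanchnic": 0.20,
    }
    r_prox_arch = 0.030
    r_prox_artery = 0.030
    r_parallel = 1.28 - (r_prox_arch + r_prox_artery)  # 1.22
    comps = [
        VascularCompartment("aortic_arch", 0.640, r_prox_arch, 60.0),
        VascularCompartment("systemic_artery", 0.036, r_prox_artery, 150.0),
    ]
    for name in DISTAL_COMPARTMENTS:
        r_branch = r_parallel / flow_fraction[name]
        comps.append(VascularCompartment(
            name, distal_c[name], 0.92 * r_branch, 110.0, resistance_in=0.08 * r_branch))
    comps += [
        VascularCompartment("systemic_vein", 80.0, 0.045, 2490.0),
        VascularCompartment("thoracic_vein", 25.0, 0.025, 250.0),
        VascularCompartment("pulmonary_artery", 4.5, 0.070, 50.0),
        VascularCompartment("pulmonary_vein", 9.0, 0.006, 350.0),
    ]
    return tuple(comps)


def default_config(heart_rate: float = 80.0,
                   total_blood_volume: float = 5300.0) -> ModelConfig:
    """The normal human-scaled configuration (C_A 0.7 ml/mmHg, R_T 1.28 mmHg*s/ml)."""
    return ModelConfig(
        heart_rate=heart_rate,
        total_blood_volume=total_blood_volume,
        chambers=_chamber_defaults(heart_rate),
        compartments=_compartment_defaults(),
    )
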