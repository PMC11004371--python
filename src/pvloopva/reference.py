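"""Packaged published reference values and comparison helpers.

The four tables below are the read-only study values this package aims to
reproduce in shape and direction: steady-state hemodynamics and fitted
relation slopes across five compliance settings at 80 bpm (phase I) and
across three pacing rates at the normal and stiff settings (phase II).
They are used for reporting and direction checks only, never as inputs to
any fit or simulation.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "TABLE1",
    "TABLE2",
    "TABLE3",
    "TABLE4",
    "PHASE1_DIRECTIONS",
    "PHASE2_DIRECTIONS",
    "percent_change",
    "compare_to_paper",
]

_LEVELS = ["normal", "90pct", "80pct", "60pct", "stiff"]

#: Phase I steady-state hemodynamics by compliance level (80 bpm).
TABLE1 = pd.DataFrame({
    "EDV_ml": [100.5, 110.9, 116.7, 124.7, 140.1],
    "ESV_ml": [54.1, 61.8, 65.9, 71.4, 87.4],
    "SV_ml": [46.5, 49.1, 50.8, 53.3, 52.7],
    "SW_mmHg_ml": [3830.0, 4802.0, 5359.0, 6150.0, 7313.0],
    "Pes_mmHg": [81.7, 97.8, 105.5, 113.7, 133.6],
    "LVEDP_mmHg": [5.0, 5.9, 6.3, 7.0, 8.4],
    "dPdtmax_mmHg_s": [1621.0, 1859.0, 1967.0, 2074.0, 2057.0],
    "PP_mmHg": [33.4, 38.8, 44.0, 56.0, 106.6],
    "ArtCa_ml_mmHg": [0.57, 0.50, 0.48, 0.47, 0.39],
}, index=pd.Index(_LEVELS, name="level"))

#: Phase I relation slopes and mechanical efficiency by compliance level.
TABLE2 = pd.DataFrame({
    "ESPVR": [1.8, 1.76, 1.75, 1.67, 1.57],
    "dPdt_EDV": [16.9, 17.2, 17.1, 16.7, 14.1],
    "PRSW": [71.4, 81.6, 86.1, 91.4, 94.8],
    "EDV_PVA": [91.7, 108.3, 117.0, 128.5, 154.7],
    "ME_pct": [71.1, 68.2, 67.0, 66.1, 60.5],
}, index=pd.Index(_LEVELS, name="level"))

_PHASE2_IDX = pd.MultiIndex.from_product(
    [["normal", "stiff"], [60.0, 100.0, 140.0]], names=["level", "heart_rate"])

#: Phase II steady-state hemodynamics (normal and stiff at 60/100/140 bpm).
TABLE3 = pd.DataFrame({
    "EDV_ml": [113.2, 86.9, 75.4, 159.6, 123.2, 75.4],
    "ESV_ml": [54.7, 49.6, 48.6, 92.9, 78.3, 48.6],
    "SV_ml": [58.5, 37.3, 26.7, 66.6, 44.8, 26.7],
    "Pes_mmHg": [82.8, 73.3, 72.1, 141.1, 119.4, 72.1],
    "LVEDP_mmHg": [5.5, 5.6, 6.3, 9.9, 8.3, 9.4],
    "PP_mmHg": [31.1, 25.4, 22.4, 77.5, 62.4, 56.6],
    "ArtCa_ml_mmHg": [0.71, 0.51, 0.37, 0.47, 0.38, 0.28],
    "dPdtmax_mmHg_s": [1086.0, 1003.0, 1050.0, 1357.0, 1260.0, 1403.0],
    "SW_mmHg_ml": [5078.0, 2788.0, 1923.0, 10322.0, 5684.0, 3989.0],
}, index=_PHASE2_IDX)

#: Phase II relation slopes and mechanical efficiency.
TABLE4 = pd.DataFrame({
    "ESPVR": [1.75, 1.99, 2.0, 1.45, 1.75, 1.92],
    "dPdt_EDV": [7.3, 10.1, 14.0, 6.5, 9.3, 12.9],
    "PRSW": [82.5, 63.8, 56.5, 118.5, 72.7, 54.6],
    "EDV_PVA": [100.6, 83.2, 79.1, 182.1, 141.0, 131.2],
    "ME_pct": [76.4, 69.9, 62.6, 65.8, 60.7, 53.2],
}, index=_PHASE2_IDX)

#: Expected sign of each metric's trend from normal to stiff at 80 bpm.
PHASE1_DIRECTIONS = {
    "EDV_ml": +1, "ESV_ml": +1, "SW_mmHg_ml": +1, "Pes_mmHg": +1,
    "LVEDP_mmHg": +1, "PP_mmHg": +1, "ArtCa_ml_mmHg": -1, "ME_pct": -1,
    "EDV_PVA": +1,
}

#: Expected sign of each metric's trend from 60 to 140 bpm within a setting.
PHASE2_DIRECTIONS = {
    "EDV_ml": -1, "ESV_ml": -1, "SV_ml": -1, "SW_mmHg_ml": -1,
    "ESPVR": +1, "dPdt_EDV": +1, "PRSW": -1, "ME_pct": -1,
}


def percent_change(from_value: float, to_value: float) -> float:
    """Signed percent change 100 * (to - from) / from."""
    if from_value == 0:
        raise ValueError("percent change undefined from a zero baseline")
    return 100.0 * (to_value - from_value) / from_value


def _monotone(values, sign: int) -> bool:
    vals = list(values)
    pairs = zip(vals, vals[1:])
    if sign > 0:
        return all(b > a for a, b in pairs)
    return all(b < a for a, b in pairs)


def compare_to_paper(study: pd.DataFrame, phase: int) -> dict:
    """Compare a computed study table against the packaged reference values.

    Returns per-cell signed relative deviations, a direction-agreement flag
    per metric (monotone along the stiffness axis for phase 1, along the
    rate axis within each setting for phase 2), and a list of keys present
    in the reference but missing from the study table.
    """
    if phase == 1:
        ref = TABLE1.join(TABLE2)
        df = study.set_index("level")
        directions = PHASE1_DIRECTIONS
        axes = [list(ref.index)]
    elif phase == 2:
        ref = TABLE3.join(TABLE4)
        df = study.set_index(["level", "heart_rate"])
        directions = PHASE2_DIRECTIONS
        axes = [[("normal", h) for h in (60.0, 100.0, 140.0)],
                [("stiff", h) for h in (60.0, 100.0, 140.0)]]
    else:
        raise ValueError("phase must be 1 or 2")

    missing = [k for k in ref.index if k not in df.index]
    present = [k for k in ref.index if k in df.index]
    deviation = pd.DataFrame(index=present, columns=ref.columns, dtype=float)
    for col in ref.columns:
        if col not in df.columns:
            continue
        for key in present:
            ours, theirs = df.at[key, col], ref.at[key, col]
            if ours is not None and pd.notna(ours):
                deviation.at[key, col] = (float(ours) - theirs) / theirs

    direction_ok: dict[str, bool] = {}
    for col, sign in directions.items():
        if col not in df.columns:
            direction_ok[col] = False
            continue
        ok = True
        for axis in axes:
            keys = [k for k in axis if k in df.index]
            if len(keys) < 2:
                ok = False
                break
            ok = ok and _monotone([float(df.at[k, col]) for k in keys], sign)
        direction_ok[col] = ok

    return {
        "phase": phase,
        "deviation": deviation,
        "direction_ok": direction_ok,
        "all_directions_agree": all(direction_ok.values()),
        "missing_keys": missing,
    }
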