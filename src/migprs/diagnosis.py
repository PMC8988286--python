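"""Deterministic ICHD-3 rule engine over a boolean symptom battery.

Maps per-individual symptom indicators to the main migraine diagnostic
criteria (A-D with sub-criteria D1/D2), non-exclusive diagnostic flags,
a mutually exclusive severity ladder, and a symptom-count complexity score.

Criteria, on a complete battery row:

* A - at least five headache attacks (``attacks_ge5``);
* B - attack duration 4-72 h (``duration_4_72h``);
* C - at least two of {unilateral, pulsating, moderate-or-severe pain,
  aggravation by physical activity};
* D1 - nausea or vomiting; D2 - photophobia and phonophobia;
  D - D1 or D2.

Diagnoses: migraine without aura (MwoA) requires all of A-D; migraine with
aura (MwA) is driven by visual/sensory/speech aura indicators and
hemiplegic migraine (HM) by motor aura, neither requiring the full headache
criteria; "probable migraine" misses exactly one of A-D (and has no aura
diagnosis); "headache" misses more than one but reports some headache
symptom; "no headache" reports none. The exclusive ladder orders
no_headache < headache < probable_migraine < mwoa < mwa < hm and each
individual receives the highest rung whose flag is set.

Attack-count requirements (>=5 for MwoA, >=2 for aura diagnoses) are
encoded in the battery indicators themselves, which the simulator sets; the
engine treats the indicators as given. Osmophobia travels in the battery but
enters neither the criteria nor the symptom count (not part of ICHD-3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "HEADACHE_SYMPTOMS",
    "AURA_COLUMNS",
    "BATTERY_COLUMNS",
    "PAIN_FEATURES",
    "LADDER",
    "MIGRAINE_LABELS",
    "coerce_battery",
    "evaluate_criteria",
    "classify",
    "symptom_count",
    "diagnose",
]

# The ten headache symptoms that enter criteria and the complexity count.
HEADACHE_SYMPTOMS = [
    "attacks_ge5",
    "duration_4_72h",
    "unilateral",
    "pulsating",
    "moderate_or_severe",
    "activity_aggravates",
    "nausea",
    "vomiting",
    "photophobia",
    "phonophobia",
]
PAIN_FEATURES = ["unilateral", "pulsating", "moderate_or_severe", "activity_aggravates"]
AURA_COLUMNS = ["aura_visual", "aura_sensory", "aura_speech", "aura_motor"]
# Full battery: headache symptoms, osmophobia (carried but outside ICHD-3), auras.
BATTERY_COLUMNS = HEADACHE_SYMPTOMS + ["osmophobia"] + AURA_COLUMNS
# Fields that count as "reporting headache" for the no-headache rung.
HEADACHE_FIELDS = HEADACHE_SYMPTOMS + ["osmophobia"]

LADDER = ["no_headache", "headache", "probable_migraine", "mwoa", "mwa", "hm"]
MIGRAINE_LABELS = ("mwoa", "mwa", "hm")

CRITERIA_COLUMNS = ["A", "B", "C", "D", "D1", "D2"]
FLAG_COLUMNS = ["no_headache", "headache", "probable_migraine", "mwoa", "mwa", "hm"]


def _as_frame(battery) -> pd.DataFrame:
    if isinstance(battery, pd.Series):
        battery = battery.to_frame().T
    return battery


def coerce_battery(battery: pd.DataFrame) -> pd.DataFrame:
    """Return a complete boolean battery: missing columns/answers become False."""
    battery = _as_frame(battery)
    out = pd.DataFrame(index=battery.index)
    for col in BATTERY_COLUMNS:
        if col in battery.columns:
            vals = battery[col].to_numpy(dtype=object)
            out[col] = np.array([bool(v) if not pd.isna(v) else False for v in vals], dtype=bool)
        else:
            out[col] = False
    return out


def evaluate_criteria(battery) -> pd.DataFrame:
    """Evaluate ICHD-3 criteria A, B, C, D (with D1/D2) for each battery row."""
    b = coerce_battery(battery)
    crit = pd.DataFrame(index=b.index)
    crit["A"] = b["attacks_ge5"]
    crit["B"] = b["duration_4_72h"]
    crit["C"] = b[PAIN_FEATURES].sum(axis=1) >= 2
    crit["D1"] = b["nausea"] | b["vomiting"]
    crit["D2"] = b["photophobia"] & b["phonophobia"]
    crit["D"] = crit["D1"] | crit["D2"]
    return crit[CRITERIA_COLUMNS]


def classify(criteria: pd.DataFrame, battery) -> pd.DataFrame:
    """Assign non-exclusive diagnostic flags and the exclusive ladder label.

    Returns a DataFrame with one boolean column per flag plus ``label``
    (an ordered categorical over the severity ladder).
    """
    b = coerce_battery(battery)
    if not criteria.index.equals(b.index):
        criteria = criteria.set_axis(b.index)
    abcd = criteria[["A", "B", "C", "D"]].to_numpy(dtype=bool)
    n_missing = (~abcd).sum(axis=1)
    any_headache = b[HEADACHE_FIELDS].any(axis=1).to_numpy()

    flags = pd.DataFrame(index=b.index)
    flags["mwoa"] = n_missing == 0
    flags["mwa"] = b[["aura_visual", "aura_sensory", "aura_speech"]].any(axis=1)
    flags["hm"] = b["aura_motor"]
    aura_dx = (flags["mwa"] | flags["hm"]).to_numpy()
    flags["probable_migraine"] = (n_missing == 1) & ~aura_dx
    flags["headache"] = (n_missing >= 2) & any_headache
    flags["no_headache"] = ~any_headache

    label = np.empty(len(b), dtype=object)
    label[:] = "no_headache"
    for rung in LADDER:  # ascending: later assignments win
        label[flags[rung].to_numpy()] = rung
    out = flags[FLAG_COLUMNS].copy()
    out["label"] = pd.Categorical(label, categories=LADDER, ordered=True)
    return out


def symptom_count(battery) -> pd.Series:
    """Migraine complexity: sum of the 10 headache symptoms + visual + motor aura."""
    b = coerce_battery(battery)
    counted = HEADACHE_SYMPTOMS + ["aura_visual", "aura_motor"]
    return b[counted].sum(axis=1).astype(int).rename("symptom_count")


def diagnose(battery: pd.DataFrame) -> pd.DataFrame:
    """Convenience: criteria + flags + exclusive label + symptom count in one table."""
    b = coerce_battery(battery)
    crit = evaluate_criteria(b)
    cls = classify(crit, b)
    return pd.concat([crit, cls, symptom_count(b)], axis=1)
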