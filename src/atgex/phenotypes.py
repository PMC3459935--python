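"""Derived clinical phenotypes: BMI, HOMA-IR, metabolic-syndrome status and
weight-change groups.

Metabolic syndrome follows the harmonized (2009 joint interim statement)
definition — at least 3 of 5 criteria on waist circumference (Europid
cutoffs), triglycerides, HDL-cholesterol, blood pressure and fasting
glucose.  Medication-based criteria are not applied.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

WAIST_CUTOFF = {"M": 94.0, "F": 80.0}      # cm, Europid
HDL_CUTOFF = {"M": 1.03, "F": 1.29}        # mM, low-HDL criterion is '<'
TG_CUTOFF = 1.7                            # mM
SBP_CUTOFF, DBP_CUTOFF = 130.0, 85.0       # mmHg
GLUCOSE_CUTOFF = 5.6                       # mM


def derive_bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) / height (m) squared."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return weight / height ** 2


def derive_homa_ir(glucose: float, insulin: float) -> float:
    """Homeostatic model assessment of insulin resistance:
    glucose (mM) x insulin (mU/l) / 22.5."""
    if glucose < 0 or insulin < 0:
        raise ValueError("glucose and insulin must be non-negative")
    return glucose * insulin / 22.5


def classify_mets(waist: float, triglycerides: float, hdl: float,
                  sbp: float, dbp: float, glucose: float, sex: str,
                  ) -> bool | None:
    """Harmonized metabolic-syndrome flag; ``None`` when a component is
    missing (never silently False)."""
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    components = [waist, triglycerides, hdl, sbp, dbp, glucose]
    if any(c is None or (isinstance(c, float) and np.isnan(c))
           for c in components):
        return None
    n = 0
    n += waist >= WAIST_CUTOFF[sex]
    n += triglycerides >= TG_CUTOFF
    n += hdl < HDL_CUTOFF[sex]
    n += (sbp >= SBP_CUTOFF) or (dbp >= DBP_CUTOFF)
    n += glucose >= GLUCOSE_CUTOFF
    return n >= 3


def assign_weight_change_group(w1: float, w2: float, w3: float) -> str:
    """Classify the weight-maintenance trajectory of one subject.

    ``regain``: regained at least 50% of the weight lost during calorie
    restriction; ``loss``: lost at least another 50% of it; ``neither``
    otherwise.  Boundaries are inclusive.  Subjects who did not lose weight
    during calorie restriction are ``not_applicable``.
    """
    if w2 >= w1:
        return "not_applicable"
    lost = w1 - w2
    if (w3 - w2) >= 0.5 * lost:
        return "regain"
    if (w2 - w3) >= 0.5 * lost:
        return "loss"
    return "neither"


def derive_phenotypes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Extend a subject-visit cohort table with bmi, homa_ir, mets and the
    per-subject weight_change_group (computed from the three visit weights,
    attached to every row of the subject)."""
    out = cohort.copy()
    out["bmi"] = out["weight"] / out["height"] ** 2
    out["homa_ir"] = out["glucose"] * out["insulin"] / 22.5
    out["mets"] = [
        classify_mets(r.waist, r.triglycerides, r.hdl, r.sbp, r.dbp,
                      r.glucose, r.sex)
        for r in out.itertuples()
    ]

    groups = {}
    for sid, sub in out.groupby("subject_id"):
        w = sub.set_index("cid")["weight"]
        if {1, 2, 3} <= set(w.index):
            groups[sid] = assign_weight_change_group(w[1], w[2], w[3])
        else:
            groups[sid] = "not_applicable"
    out["weight_change_group"] = out["subject_id"].map(groups)
    return out
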