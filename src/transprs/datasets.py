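"""Published target-cohort summaries and a synthetic demo phenotype table.

The module carries, as plain constants, the printed demographic and
smoking summaries of the Japanese schizophrenia family-study target
cohort (146 healthy controls, 56 unaffected first-degree relatives, 130
patients) that the worked examples and the contingency/ANOVA statistics
operate on. ``build_demo_phenotypes`` constructs a fully synthetic
individual-level table whose margins reproduce those printed counts
exactly — it is a stand-in for the non-public genotype-linked phenotype
file, useful for exercising readers and the survival analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PHENOTYPE_COLUMNS

__all__ = [
    "TARGET_GROUP_SIZES", "EVER_NEVER", "CURRENT_FORMER", "SEX_MF",
    "AGE_SUMMARY", "EDUCATION_SUMMARY", "AGE_INITIATION_SUMMARY",
    "CPD_SUMMARY", "LATE_INITIATION", "ONSET_SUMMARY",
    "build_demo_phenotypes",
]

#: per-group sample sizes (HC / FR / SCZ)
TARGET_GROUP_SIZES = {"HC": 146, "FR": 56, "SCZ": 130}

#: ever / never regular smokers
EVER_NEVER = {"HC": (36, 110), "FR": (12, 44), "SCZ": (33, 97)}

#: current / former smokers among ever-smokers
CURRENT_FORMER = {"HC": (24, 12), "FR": (2, 10), "SCZ": (29, 4)}

#: males / females
SEX_MF = {"HC": (97, 49), "FR": (18, 38), "SCZ": (50, 80)}

#: (n, mean, sd) per group
AGE_SUMMARY = {"HC": (146, 37.2, 14.1), "FR": (56, 56.8, 15.6),
               "SCZ": (130, 42.9, 13.1)}
EDUCATION_SUMMARY = {"HC": (146, 16.1, 2.4), "FR": (56, 12.8, 2.1),
                     "SCZ": (130, 12.6, 2.2)}
AGE_INITIATION_SUMMARY = {"HC": (36, 20.0, 2.2), "FR": (12, 21.3, 2.8),
                          "SCZ": (33, 22.6, 6.4)}
CPD_SUMMARY = {"HC": (36, 16.4, 10.3), "FR": (12, 19.0, 14.4),
               "SCZ": (33, 21.3, 14.3)}
ONSET_SUMMARY = (130, 26.9, 10.6)

#: ever-smokers initiating strictly after age 20: (n_late, n_ever)
LATE_INITIATION = {"HC": (5, 36), "FR": (5, 12), "SCZ": (12, 33)}


def _spread(n: int, mean: float, sd: float, rng: np.random.Generator,
            lo: float, hi: float) -> np.ndarray:
    """n values with approximately the requested mean/sd, clipped."""
    v = np.clip(np.round(rng.normal(mean, sd, size=n)), lo, hi)
    return v


def build_demo_phenotypes(seed: int = 7) -> pd.DataFrame:
    """Synthetic individual-level phenotype table matching the published
    margins exactly.

    Group sizes, sex counts, ever/never, current/former, and
    late-initiation (> 20 years) counts reproduce the printed table;
    continuous variables are drawn around the printed means. Entirely
    synthetic — no individual-level study data enters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in TARGET_GROUP_SIZES.items():
        n_m, n_f = SEX_MF[group]
        sex = np.array(["M"] * n_m + ["F"] * n_f)
        n_ever, n_never = EVER_NEVER[group]
        ever = np.array([1] * n_ever + [0] * n_never)
        rng.shuffle(ever)
        age = _spread(n, *AGE_SUMMARY[group][1:], rng, 20, 90)
        edu = _spread(n, *EDUCATION_SUMMARY[group][1:], rng, 6, 22)

        n_late, _ = LATE_INITIATION[group]
        _, mu_i, sd_i = AGE_INITIATION_SUMMARY[group]
        late_vals = np.clip(np.round(rng.normal(max(mu_i + sd_i, 23), 2.0,
                                                size=n_late)), 21, 45)
        early_vals = np.clip(np.round(rng.normal(min(mu_i, 19), 1.5,
                                                 size=n_ever - n_late)), 15, 20)
        init = np.concatenate([late_vals, early_vals])
        rng.shuffle(init)

        _, mu_c, sd_c = CPD_SUMMARY[group]
        cpd = _spread(n_ever, mu_c, sd_c, rng, 1, 80)
        n_cur, n_for = CURRENT_FORMER[group]
        current = np.array([1] * n_cur + [0] * n_for)
        rng.shuffle(current)

        onset = None
        if group == "SCZ":
            onset = _spread(n, *ONSET_SUMMARY[1:], rng, 13, 60)
            onset = np.minimum(onset, age)

        k = 0
        for i in range(n):
            is_ever = bool(ever[i])
            rows.append({
                "sample_id": f"{group}{i:04d}", "group": group,
                "age": float(age[i]), "sex": sex[i],
                "education": float(edu[i]), "ever_smoker": int(ever[i]),
                "age_initiation": float(init[k]) if is_ever else np.nan,
                "cpd": float(cpd[k]) if is_ever else np.nan,
                "current_smoker": float(current[k]) if is_ever else np.nan,
                "onset_age": float(onset[i]) if group == "SCZ" else np.nan,
            })
            if is_ever:
                k += 1
    df = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    # an ever-smoker's initiation age cannot exceed their interview age
    df["age_initiation"] = np.minimum(df["age_initiation"],
                                      df["age"].where(df["ever_smoker"] == 1) - 1)
    return df
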