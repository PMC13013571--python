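"""Case/control cohort construction from a labelled record registry.

The cohort logic mirrors a CONSORT-style selection from a large ECG
registry (the motivating accession is PTB-XL):

* **cases** — every sinus-rhythm (SR) record of every patient who has at
  least one AFIB-labelled record *and* at least one SR record; the AFIB
  records themselves are never used (the classifier sees only sinus
  rhythm).
* **controls** — SR records of patients with no AFIB record and no
  diagnostic-superclass comorbidity, matched 1:1 to case records on sex
  (exact) and age (same decade band), without replacement.
* **test groups** — the remaining non-cohort SR records: group 1 from
  patients carrying at least one comorbidity superclass, group 2 from
  patients carrying none.

All selection is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import _split_labels

AFIB, SR = "AFIB", "SR"

#: Decade bands accepted for matching; ages outside are rejected.
DECADE_BANDS = tuple((lo, lo + 10) for lo in range(20, 90, 10))


@dataclass
class CohortSpec:
    seed: int = 0
    decade_bands: tuple = DECADE_BANDS
    require_prior_af: bool = False

    unmatched: list = field(default_factory=list)  # populated by match_controls


def _parse_registry(meta: pd.DataFrame) -> pd.DataFrame:
    frame = meta.copy().reset_index(drop=True)
    frame["record_id"] = frame["record_id"].astype(str)
    frame["patient_id"] = frame["patient_id"].astype(str)
    frame["rhythm_set"] = frame["rhythm_labels"].map(_split_labels)
    frame["superclass_set"] = frame["superclass_labels"].map(_split_labels)
    return frame


def _decade_band(age: float, bands) -> tuple | None:
    for lo, hi in bands:
        if lo <= age < hi:
            return (lo, hi)
    return None


def select_cases(meta: pd.DataFrame, require_prior_af: bool = False) -> pd.DataFrame:
    """All SR records of patients having both an AFIB and an SR record.

    With ``require_prior_af``, SR records are kept only when recorded after
    the patient's earliest AFIB record (needs a ``recording_date`` column).
    """
    frame = _parse_registry(meta)
    has_afib = frame.groupby("patient_id")["rhythm_set"].apply(
        lambda sets: any(AFIB in s for s in sets))
    has_sr = frame.groupby("patient_id")["rhythm_set"].apply(
        lambda sets: any(SR in s for s in sets))
    qualifying = set(has_afib[has_afib & has_sr].index)
    cases = frame[frame["patient_id"].isin(qualifying)
                  & frame["rhythm_set"].map(lambda s: SR in s)]
    if require_prior_af:
        if "recording_date" not in frame.columns:
            raise ValueError("require_prior_af needs a recording_date column")
        afib_first = (frame[frame["rhythm_set"].map(lambda s: AFIB in s)]
                      .groupby("patient_id")["recording_date"].min())
        cases = cases[cases.apply(
            lambda row: row["recording_date"] >= afib_first[row["patient_id"]],
            axis=1)]
    return cases.reset_index(drop=True)


def control_pool(meta: pd.DataFrame) -> pd.DataFrame:
    """SR records of patients with no AFIB record and no comorbidity."""
    frame = _parse_registry(meta)
    grouped = frame.groupby("patient_id")
    no_afib = grouped["rhythm_set"].apply(lambda sets: not any(AFIB in s for s in sets))
    no_comorb = grouped["superclass_set"].apply(lambda sets: not any(sets))
    eligible = set(no_afib[no_afib & no_comorb].index)
    pool = frame[frame["patient_id"].isin(eligible)
                 & frame["rhythm_set"].map(lambda s: SR in s)]
    return pool.reset_index(drop=True)


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame,
                   spec: CohortSpec | None = None) -> pd.DataFrame:
    """Match one control record to each case record on sex and decade band.

    Sampling is without replacement; within a stratum, candidates at the
    minimum absolute age difference are drawn at random (seeded), with a
    preference for control patients not yet used so that a second record
    from the same patient is taken only when a stratum would otherwise be
    exhausted.  Unmatched cases are listed in ``spec.unmatched`` and the
    run continues.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    pool = pool.copy().reset_index(drop=True)
    used_records: set[str] = set()
    used_patients: set[str] = set()
    spec.unmatched = []
    matches = []
    for _, case in cases.iterrows():
        band = _decade_band(case["age"], spec.decade_bands)
        if band is None:
            warnings.warn(f"case {case['record_id']} age {case['age']} outside "
                          f"matching bands; unmatched")
            spec.unmatched.append(case["record_id"])
            continue
        lo, hi = band
        stratum = pool[(pool["sex"] == case["sex"])
                       & (pool["age"] >= lo) & (pool["age"] < hi)
                       & ~pool["record_id"].isin(used_records)]
        if stratum.empty:
            spec.unmatched.append(case["record_id"])
            continue
        fresh = stratum[~stratum["patient_id"].isin(used_patients)]
        candidates = fresh if not fresh.empty else stratum
        diffs = (candidates["age"] - case["age"]).abs()
        best = candidates[diffs == diffs.min()].sort_values("patient_id")
        chosen = best.iloc[int(rng.integers(len(best)))]
        used_records.add(chosen["record_id"])
        used_patients.add(chosen["patient_id"])
        row = chosen.to_dict()
        row["matched_case_id"] = case["record_id"]
        matches.append(row)
    return pd.DataFrame(matches).reset_index(drop=True)


def build_test_groups(meta: pd.DataFrame, cohort_record_ids: set[str],
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the remaining SR records into comorbidity / healthy test groups.

    Group 1: SR records of non-case patients with >= 1 comorbidity
    superclass; group 2: SR records of non-case patients with none, minus
    records already used as matched controls.  Both are disjoint from the
    training cohort.
    """
    frame = _parse_registry(meta)
    case_patients = set(select_cases(meta)["patient_id"])
    rest = frame[~frame["patient_id"].isin(case_patients)
                 & frame["rhythm_set"].map(lambda s: SR in s)
                 & ~frame["record_id"].isin(cohort_record_ids)]
    has_comorb = rest.groupby("patient_id")["superclass_set"].apply(
        lambda sets: any(bool(s) for s in sets))
    comorb_patients = set(has_comorb[has_comorb].index)
    group1 = rest[rest["patient_id"].isin(comorb_patients)].reset_index(drop=True)
    group2 = rest[~rest["patient_id"].isin(comorb_patients)].reset_index(drop=True)
    return group1, group2


def build_cohort(meta: pd.DataFrame, spec: CohortSpec | None = None) -> pd.DataFrame:
    """Full pipeline: cases + matched controls as one manifest frame.

    Columns: record_id, patient_id, arm ("case"/"control"), matched_case_id.
    """
    spec = spec or CohortSpec()
    cases = select_cases(meta, require_prior_af=spec.require_prior_af)
    controls = match_controls(cases, control_pool(meta), spec)
    case_part = cases[["record_id", "patient_id"]].copy()
    case_part["arm"] = "case"
    case_part["matched_case_id"] = ""
    if len(controls):
        ctrl_part = controls[["record_id", "patient_id", "matched_case_id"]].copy()
        ctrl_part["arm"] = "control"
    else:
        ctrl_part = pd.DataFrame(columns=["record_id", "patient_id",
                                          "matched_case_id", "arm"])
    manifest = pd.concat([case_part, ctrl_part], ignore_index=True)
    return manifest[["record_id", "patient_id", "arm", "matched_case_id"]]


def consort_counts(meta: pd.DataFrame, spec: CohortSpec | None = None) -> dict:
    """CONSORT-style count log for the whole selection."""
    spec = spec or CohortSpec()
    cases = select_cases(meta, require_prior_af=spec.require_prior_af)
    controls = match_controls(cases, control_pool(meta), spec)
    cohort_ids = set(cases["record_id"]) | set(controls.get("record_id", []))
    group1, group2 = build_test_groups(meta, cohort_ids)
    cohort_patients = (set(cases["patient_id"])
                       | set(controls["patient_id"]) if len(controls)
                       else set(cases["patient_id"]))
    return {
        "total_records": len(meta),
        "case_patients": cases["patient_id"].nunique(),
        "case_records": len(cases),
        "control_records": len(controls),
        "cohort_records": len(cases) + len(controls),
        "cohort_patients": len(cohort_patients),
        "unmatched_cases": len(spec.unmatched),
        "test_group_1_records": len(group1),
        "test_group_1_patients": group1["patient_id"].nunique() if len(group1) else 0,
        "test_group_2_records": len(group2),
        "test_group_2_patients": group2["patient_id"].nunique() if len(group2) else 0,
    }
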