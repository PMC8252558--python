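"""Cohort eligibility filters and patient-level correlates/outcomes.

Eligibility for the severe-mental-illness cohort requires: at least one
ICD-10 diagnosis in F20–F29 (non-organic psychotic disorders) or F30–F31
(bipolar disorder), first contact with services inside the study window
with at least one year of follow-up to the window end, and at least one
HoNOS assessment.  Correlates derived here: lifetime moderate–severe HoNOS
item flags, comorbid diagnosis flags (depression, PTSD, personality
disorder), and admission outcomes (any admission; admission days per year,
computed on merged episode intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date

import pandas as pd

STUDY_WINDOW = (date(2009, 1, 1), date(2017, 12, 31))
MIN_FOLLOW_UP_DAYS = 365

#: HoNOS items consumed by the analysis (subset of the 12-item scale)
HONOS_ITEMS = (
    "aggression",
    "self_harm",
    "substance_misuse",
    "cognitive",
    "physical_illness",
    "hallucinations_delusions",
    "depressed_mood",
    "other_symptoms",
    "relationships",
    "adl",
    "living_conditions",
    "occupation",
)
ANALYSIS_ITEMS = (
    "substance_misuse",
    "self_harm",
    "depressed_mood",
    "hallucinations_delusions",
    "aggression",
    "relationships",
    "living_conditions",
)
DEFAULT_HONOS_THRESHOLD = 3  # 3 = moderately severe on the 0-4 anchors

SMI_CATEGORIES = tuple(f"F2{i}" for i in range(10)) + ("F30", "F31")


def _icd10_category(code: str) -> str | None:
    """Return the 3-character ICD-10 category, or None when unparseable."""
    code = str(code).strip().upper()
    if len(code) >= 3 and code[0].isalpha() and code[1:3].isdigit():
        return code[:3]
    return None


def is_smi_code(code: str) -> bool:
    cat = _icd10_category(code)
    if cat is None:
        warnings.warn(f"unparseable ICD-10 code {code!r}; skipped", stacklevel=2)
        return False
    return cat in SMI_CATEGORIES


def filter_cohort(
    registry: pd.DataFrame,
    honos: pd.DataFrame,
    diagnoses: pd.DataFrame,
    window: tuple[date, date] = STUDY_WINDOW,
) -> pd.DataFrame:
    """Apply the eligibility filters; returns the eligible registry rows.

    Patients with a missing first-contact date are dropped (follow-up time
    cannot be computed for them); the caller is expected to count them in
    the cohort-flow accounting.
    """
    start, end = window
    smi_ids = {
        pid
        for pid, code in zip(diagnoses["patient_id"], diagnoses["code"])
        if is_smi_code(code)
    }
    honos_ids = set(honos["patient_id"].unique())
    fc = pd.to_datetime(registry["first_contact_date"], errors="coerce")
    ok = (
        registry["patient_id"].isin(smi_ids)
        & registry["patient_id"].isin(honos_ids)
        & fc.notna()
        & (fc.dt.date >= start)
        & (fc.dt.date <= end)
        & ((pd.Timestamp(end) - fc).dt.days >= MIN_FOLLOW_UP_DAYS)
    )
    return registry.loc[ok.to_numpy()].copy()


def follow_up_years(first_contact: date, window_end: date = STUDY_WINDOW[1]) -> float:
    """Follow-up denominator: first contact to the study window end."""
    return (window_end - first_contact).days / 365.25


def dichotomize_honos(
    honos: pd.DataFrame,
    threshold: int = DEFAULT_HONOS_THRESHOLD,
    items: tuple[str, ...] = ANALYSIS_ITEMS,
) -> pd.DataFrame:
    """Lifetime presence of each item at moderate–severe level.

    A patient's flag for an item is true when *any* of their assessments
    scores that item at or above ``threshold``.  Scores must lie in 0–4.
    """
    scores = honos[list(items)]
    if ((scores < 0) | (scores > 4)).any().any():
        raise ValueError("HoNOS item scores must be in 0-4")
    flags = scores.ge(threshold).groupby(honos["patient_id"]).any()
    return flags.astype(bool)


def comorbidity_flags(codes: list[str]) -> dict[str, bool]:
    """Comorbid diagnosis flags from ICD-10 codes.

    MDD: F32–F33 (depressive episode / recurrent depressive disorder);
    PTSD: F43.1; personality disorders: F60–F61.
    """
    cats = {_icd10_category(c) for c in codes} - {None}
    full = {str(c).strip().upper().replace(".", "") for c in codes}
    return {
        "mdd": bool(cats & {"F32", "F33"}),
        "ptsd": any(c.startswith("F431") for c in full),
        "pd": bool(cats & {"F60", "F61"}),
    }


@dataclass
class AdmissionOutcome:
    any_admission: bool
    days: float
    days_per_year: float


def merge_episodes(episodes: list[tuple[date, date]]) -> list[tuple[date, date]]:
    """Union of admission intervals; adjacent/overlapping episodes merge."""
    for s, e in episodes:
        if e < s:
            raise ValueError(f"episode end {e} before start {s}")
    merged: list[tuple[date, date]] = []
    for s, e in sorted(episodes):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def derive_admission_outcomes(
    episodes: list[tuple[date, date]],
    follow_up_yrs: float,
) -> AdmissionOutcome:
    """Any-admission flag and admission days per year of follow-up.

    Episode length is end − start in days with a 1-day minimum, so a
    same-day admission/discharge still counts as one inpatient day.
    Overlapping episodes are merged first.
    """
    if follow_up_yrs < 1:
        raise ValueError("follow-up must be at least one year")
    merged = merge_episodes(episodes)
    days = float(sum(max((e - s).days, 1) for s, e in merged))
    return AdmissionOutcome(
        any_admission=bool(merged),
        days=days,
        days_per_year=days / follow_up_yrs,
    )


def honos_prevalence_by_group(
    flags: pd.DataFrame,
    exposure: pd.Series,
    items: tuple[str, ...] = ANALYSIS_ITEMS,
) -> pd.DataFrame:
    """Per-item prevalence (%) of moderate–severe flags by exposure group."""
    df = flags.join(exposure.rename("exposed"), how="inner")
    sizes = df.groupby("exposed").size()
    if len(sizes) < 2 or (sizes == 0).any():
        raise ValueError("both exposure groups must be non-empty")
    prev = df.groupby("exposed")[list(items)].mean().T * 100.0
    prev.columns = ["no_csa" if not c else "csa" for c in prev.columns]
    prev.index.name = "honos_item"
    return prev.round(2)
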