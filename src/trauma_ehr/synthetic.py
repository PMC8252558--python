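"""Seeded synthetic EHR cohort generator.

Generates, from one integer seed, the five linked tables the analysis
pipeline consumes — registry, clinical notes, HoNOS assessments, admission
episodes, diagnoses — plus a ground-truth table used only for validation
(note-level mention labels and the patient-level CSA flag).

The generative model, in order:

1. ``true_csa ~ Bernoulli(prevalence)`` per patient.
2. Demographics drawn conditionally on CSA status: the exposed group's
   category shares are the cohort marginals tilted by per-category
   log shifts, and the unexposed group's shares are chosen so the cohort
   marginals are preserved exactly.
3. Binary outcomes (admission, antipsychotic receipt, comorbidities,
   lifetime moderate–severe HoNOS items) from per-outcome logistic models
   ``logit(p) = logit(baseline) + log_or * csa``.
4. Notes: every true-CSA patient gets exactly one unqualified positive
   mention; unexposed patients' notes may carry negated / uncertain /
   adult-onset distractor sentences at the configured rates.  Medication
   sentences with ``<dose> mg`` and od/bd/tds frequency tokens are added to
   notes of antipsychotic-receiving patients, with a small configurable
   rate of >200%-of-maximum data-entry errors.

Every note carries exactly one mention label, so detector audits against
truth are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigError, MedParams
from .features import HONOS_ITEMS, ANALYSIS_ITEMS, STUDY_WINDOW
from .meddose import load_gazetteer

WINDOW_START, WINDOW_END = STUDY_WINDOW
# latest first contact still giving >= 1 year of follow-up to the window end
_LAST_FIRST_CONTACT = WINDOW_END - timedelta(days=366)

MENTION_LABELS = ("positive", "negated", "uncertain", "adult_onset", "indeterminate", "none")

# ---------------------------------------------------------------------------
# note templates; "{age}" / "{a}"-"{b}" are filled at sampling time
# ---------------------------------------------------------------------------

POSITIVE_TEMPLATES = [
    "There is a documented history of childhood sexual abuse.",
    "In today's session she disclosed that she was sexually abused as a child.",
    "He described childhood experiences of sexual abuse during the assessment.",
    "Hx of CSA recorded in previous correspondence.",
    "Disclosed sexual abuse at age {age} by a family member.",
    "She reports being sexually abused between the ages of {a}-{b}.",
    "Was sexually abused at the age of {age}; referred to trauma service.",
]
NEGATED_TEMPLATES = [
    "Patient denied a childhood history of sexual abuse.",
    "No CSA or other childhood adversity reported.",
    "Nil CSA, nil other trauma.",
    "Denies any history of sexual abuse.",
    "No history of sexual abuse was reported at assessment.",
]
UNCERTAIN_TEMPLATES = [
    "Possible history of sexual abuse, not yet explored.",
    "? CSA - to be clarified with the care coordinator.",
    "Possible CSA mentioned by a relative; patient has not confirmed this.",
]
ADULT_TEMPLATES = [
    "She was sexually abused at age {age} while living abroad.",
    "Sexually abused at the age of {age} by a former partner.",
]
INDETERMINATE_TEMPLATES = [
    "Records refer to historical sexual abuse; age at the time could not be confirmed.",
    "Earlier letter notes historical sexual abuse, no further details available.",
]
NEUTRAL_TEMPLATES = [
    "Seen at home today; mental state settled, no risk concerns.",
    "Attended the outpatient clinic. Sleep and appetite improving.",
    "Care plan reviewed with the community team, next review in four weeks.",
    "Reports low mood this week; protective factors discussed.",
    "Family meeting held to discuss discharge planning.",
    "Did not attend; telephone contact made, will re-book.",
]

_TEMPLATES = {
    "positive": POSITIVE_TEMPLATES,
    "negated": NEGATED_TEMPLATES,
    "uncertain": UNCERTAIN_TEMPLATES,
    "adult_onset": ADULT_TEMPLATES,
    "indeterminate": INDETERMINATE_TEMPLATES,
    "none": NEUTRAL_TEMPLATES,
}

SMI_CODES = ["F20.0", "F20.3", "F22", "F23", "F25.0", "F29", "F31.2", "F31.4", "F31.8"]
SMI_WEIGHTS = [0.28, 0.08, 0.07, 0.08, 0.12, 0.07, 0.12, 0.10, 0.08]

# common tablet strengths used to quantize sampled doses onto a realistic grid
_TABLET_MG = {
    "olanzapine": 2.5, "risperidone": 1.0, "quetiapine": 25.0, "aripiprazole": 5.0,
    "haloperidol": 1.0, "clozapine": 25.0, "amisulpride": 100.0, "chlorpromazine": 25.0,
}


@dataclass
class CohortData:
    """The generated tables, keyed the way the pipeline consumes them."""

    registry: pd.DataFrame
    notes: pd.DataFrame
    honos: pd.DataFrame
    admissions: pd.DataFrame
    diagnoses: pd.DataFrame
    truth: pd.DataFrame


def conditional_category_probs(
    marginal: dict[str, float],
    shifts: dict[str, float],
    prevalence: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """Split a cohort marginal into unexposed/exposed category distributions.

    Exposed shares are the marginal tilted by ``exp(shift)`` and
    renormalized; unexposed shares are the mixture complement
    ``(m - prev * p_exposed) / (1 - prev)``, so the cohort marginal is
    preserved exactly.  Shifts large enough to drive a complement negative
    are a configuration error.
    """
    cats = list(marginal)
    tilted = np.array([marginal[c] * np.exp(shifts.get(c, 0.0)) for c in cats])
    p_exp = tilted / tilted.sum()
    if prevalence >= 1:
        return dict(zip(cats, p_exp)), dict(zip(cats, p_exp))
    p_un = (np.array([marginal[c] for c in cats]) - prevalence * p_exp) / (1 - prevalence)
    if (p_un < -1e-12).any():
        raise ConfigError("exposed_shifts too extreme for the marginal/prevalence")
    p_un = np.clip(p_un, 0, None)
    p_un = p_un / p_un.sum()
    return dict(zip(cats, p_un)), dict(zip(cats, p_exp))


def sample_binary_outcomes(
    true_csa: np.ndarray,
    effects,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw each configured binary outcome from its logistic model."""
    csa = np.asarray(true_csa, dtype=float)
    out = {}
    for name, eff in effects.items():
        logit = np.log(eff.baseline_rate / (1 - eff.baseline_rate)) + eff.log_or * csa
        p = 1 / (1 + np.exp(-logit))
        out[name] = rng.random(len(csa)) < p
    return pd.DataFrame(out)


def generate_note_text(label: str, rng: np.random.Generator) -> str:
    """One clinical-note body carrying exactly one mention of the given label.

    ``positive`` notes embed one inclusion phrase (sometimes with a
    childhood age slot); ``adult_onset`` uses an age-slot phrase with an
    adult age, and ``none`` is neutral filler.
    """
    if label not in _TEMPLATES:
        raise ValueError(f"unknown mention label {label!r}")
    tpl = _TEMPLATES[label][rng.integers(len(_TEMPLATES[label]))]
    if "{a}" in tpl:
        a = int(rng.integers(4, 13))
        b = a + int(rng.integers(1, 5))
        tpl = tpl.replace("{a}", str(a)).replace("{b}", str(b))
    elif "{age}" in tpl:
        age = int(rng.integers(4, 16)) if label == "positive" else int(rng.integers(19, 56))
        tpl = tpl.replace("{age}", str(age))
    filler = NEUTRAL_TEMPLATES[rng.integers(len(NEUTRAL_TEMPLATES))]
    return tpl if label == "none" else f"{filler} {tpl}"


def _med_sentence(
    drug: str,
    max_mg: float | None,
    fraction: float | None,
    rng: np.random.Generator,
) -> str:
    if max_mg is None:  # depot formulation: name-only mention
        return f"Receives {drug} depot fortnightly."
    if fraction is None:
        return f"Remains on {drug}."
    step = _TABLET_MG.get(drug, 1.0)
    dose = max(step, round(fraction * max_mg / step) * step)
    freq = ["od", "bd", "tds"][rng.integers(3)]
    dose_g = dose / {"od": 1, "bd": 2, "tds": 3}[freq]
    # keep the per-administration dose on the tablet grid
    dose_g = max(step, round(dose_g / step) * step)
    dose_s = f"{dose_g:g}"
    verb = ["Continue", "Commenced on", "Prescribed"][rng.integers(3)]
    return f"{verb} {drug} {dose_s} mg {freq}."


def _sample_dates(rng: np.random.Generator, start: date, end: date, n: int) -> list[date]:
    span = (end - start).days
    return [start + timedelta(days=int(d)) for d in np.sort(rng.integers(0, span + 1, n))]


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate the full synthetic cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = [f"P{i:07d}" for i in range(1, n + 1)]

    true_csa = rng.random(n) < config.csa_prevalence
    # indeterminate-only and missing-first-contact patients come from the
    # unexposed pool so ground truth stays unambiguous
    unexposed_idx = np.flatnonzero(~true_csa)
    n_ind = int(round(config.indeterminate_rate * n))
    ind_idx = set(rng.choice(unexposed_idx, size=min(n_ind, len(unexposed_idx)), replace=False).tolist())
    n_missing = int(round(config.missing_first_contact_rate * n))
    missing_idx = set(rng.choice(n, size=n_missing, replace=False).tolist()) if n_missing else set()

    # --- demographics -----------------------------------------------------
    demo: dict[str, np.ndarray] = {}
    for var, marg in config.demographic_marginals.items():
        p_un, p_exp = conditional_category_probs(
            marg, config.exposed_shifts.get(var, {}), config.csa_prevalence
        )
        cats = np.array(list(marg), dtype=object)
        col = np.empty(n, dtype=object)
        for mask, probs in ((~true_csa, p_un), (true_csa, p_exp)):
            k = int(mask.sum())
            if k:
                col[mask] = rng.choice(cats, size=k, p=[probs[c] for c in cats])
        demo[var] = col

    span = (_LAST_FIRST_CONTACT - WINDOW_START).days
    first_contact = [WINDOW_START + timedelta(days=int(d)) for d in rng.integers(0, span + 1, n)]
    age_first = np.clip(np.round(rng.normal(38, 13, n)), 16, 90).astype(int)
    followup = np.array([(WINDOW_END - fc).days / 365.25 for fc in first_contact])

    registry = pd.DataFrame({
        "patient_id": pids,
        "sex": demo["sex"],
        "ethnicity": demo["ethnicity"],
        "marital": demo["marital"],
        "imd_quartile": demo["deprivation"],
        "first_contact_date": [
            "" if i in missing_idx else fc.isoformat() for i, fc in enumerate(first_contact)
        ],
        "age_at_first_presentation": age_first,
    })

    outcomes = sample_binary_outcomes(true_csa, config.outcome_effects, rng)

    # --- diagnoses --------------------------------------------------------
    diag_rows: list[tuple[str, str]] = []
    smi_choice = rng.choice(SMI_CODES, size=n, p=np.array(SMI_WEIGHTS) / sum(SMI_WEIGHTS))
    for i, pid in enumerate(pids):
        diag_rows.append((pid, smi_choice[i]))
        if outcomes["mdd"][i]:
            diag_rows.append((pid, "F33.1" if rng.random() < 0.5 else "F32.1"))
        if outcomes["ptsd"][i]:
            diag_rows.append((pid, "F43.1"))
        if outcomes["pd"][i]:
            diag_rows.append((pid, "F60.3" if rng.random() < 0.7 else "F60.9"))
    diagnoses = pd.DataFrame(diag_rows, columns=["patient_id", "code"])

    # --- HoNOS assessments ------------------------------------------------
    honos_rows = []
    for i, pid in enumerate(pids):
        n_assess = 1 + rng.poisson(1.5)
        dates = _sample_dates(rng, first_contact[i], WINDOW_END, n_assess)
        scores = rng.integers(0, 3, size=(n_assess, len(HONOS_ITEMS)))
        for j, item in enumerate(HONOS_ITEMS):
            if item in ANALYSIS_ITEMS and outcomes[item][i]:
                scores[rng.integers(n_assess), j] = 3 + rng.integers(2)
        for k in range(n_assess):
            honos_rows.append((pid, dates[k].isoformat(), *scores[k]))
    honos = pd.DataFrame(honos_rows, columns=["patient_id", "date", *HONOS_ITEMS])

    # --- admissions -------------------------------------------------------
    adm_rows = []
    for i, pid in enumerate(pids):
        if not outcomes["admission"][i]:
            continue
        mu = config.days_per_year_log_median + config.days_per_year_exposed_shift * true_csa[i]
        dpy = float(np.exp(rng.normal(mu, config.days_per_year_log_sd)))
        total = max(1, int(round(dpy * followup[i])))
        total = min(total, int(followup[i] * 365) - 2)
        n_ep = 1 + rng.poisson(min(2.0, total / 15))
        cuts = np.sort(rng.choice(np.arange(1, total), size=min(n_ep - 1, max(total - 1, 0)), replace=False)) if total > 1 and n_ep > 1 else np.array([], dtype=int)
        durations = np.diff([0, *cuts, total])
        free = int(followup[i] * 365) - total
        gaps = np.sort(rng.integers(0, max(free, 1), size=len(durations)))
        pos = 0
        for g, dur in zip(gaps, durations):
            start = first_contact[i] + timedelta(days=int(g) + pos)
            end = start + timedelta(days=int(dur))
            if end > WINDOW_END:
                end = WINDOW_END
                start = min(start, end)
            adm_rows.append((pid, start.isoformat(), end.isoformat()))
            pos += int(dur)
    admissions = pd.DataFrame(adm_rows, columns=["patient_id", "start_date", "end_date"])

    # --- notes + truth ----------------------------------------------------
    gazetteer = {d.generic_name: d.max_daily_dose_mg for d in load_gazetteer()}
    mp: MedParams = config.med_params
    drugs = list(mp.drug_weights)
    drug_p = np.array(list(mp.drug_weights.values()), dtype=float)
    drug_p = drug_p / drug_p.sum()
    dr = config.distractor_rates
    p_distract = np.array([dr.negated, dr.uncertain, dr.adult_onset])

    note_rows = []
    truth_rows = []
    note_no = 0
    for i, pid in enumerate(pids):
        n_notes = 1 + rng.poisson(config.note_rate * followup[i])
        labels = ["none"] * n_notes
        if true_csa[i]:
            labels[rng.integers(n_notes)] = "positive"
        else:
            u = rng.random((n_notes, 3)) < p_distract
            for k in range(n_notes):
                for j, lab in enumerate(("negated", "uncertain", "adult_onset")):
                    if u[k, j]:
                        labels[k] = lab
                        break
            if i in ind_idx:
                labels = ["none" if l != "none" else l for l in labels]
                labels[rng.integers(n_notes)] = "indeterminate"
        dates = _sample_dates(rng, first_contact[i], WINDOW_END, n_notes)
        frac_base = rng.normal(
            mp.fraction_mu + mp.exposed_fraction_shift * true_csa[i], mp.fraction_sd
        )
        frac_base = float(np.clip(frac_base, 0.05, 1.95))
        for k in range(n_notes):
            note_no += 1
            nid = f"N{note_no:08d}"
            text = generate_note_text(labels[k], rng)
            if outcomes["antipsychotic"][i] and rng.random() < mp.med_sentence_rate:
                drug = drugs[rng.choice(len(drugs), p=drug_p)]
                if rng.random() < mp.dose_present_rate:
                    frac = rng.uniform(2.05, 5.0) if rng.random() < mp.dose_error_rate else frac_base
                else:
                    frac = None
                text = f"{text} {_med_sentence(drug, gazetteer[drug], frac, rng)}"
            note_rows.append((nid, pid, dates[k].isoformat(), text))
            truth_rows.append((nid, pid, labels[k], bool(true_csa[i])))

    notes = pd.DataFrame(note_rows, columns=["note_id", "patient_id", "date", "text"])
    truth = pd.DataFrame(truth_rows, columns=["note_id", "patient_id", "label", "true_csa"])
    return CohortData(registry, notes, honos, admissions, diagnoses, truth)


def make_flow_fixture(
    n_identified: int = 7030,
    n_missing_first_contact: int = 15,
    n_indeterminate: int = 15,
    n_exposed: int = 619,
) -> CohortData:
    """Deterministic miniature of the reference cohort's patient flow.

    Builds a cohort whose accounting is exact rather than sampled: a fixed
    number of patients with a missing first-contact date, a fixed number
    whose only mention is age-indeterminate, and a fixed number with an
    unqualified positive mention.  Used to exercise the pipeline's
    identified → removed → analytic bookkeeping.
    """
    if n_missing_first_contact + n_indeterminate + n_exposed > n_identified:
        raise ValueError("group sizes exceed cohort size")
    pids = [f"P{i:07d}" for i in range(1, n_identified + 1)]
    missing = set(range(n_missing_first_contact))
    ind = set(range(n_missing_first_contact, n_missing_first_contact + n_indeterminate))
    exposed = set(range(
        n_missing_first_contact + n_indeterminate,
        n_missing_first_contact + n_indeterminate + n_exposed,
    ))
    registry = pd.DataFrame({
        "patient_id": pids,
        "sex": ["F" if i % 2 else "M" for i in range(n_identified)],
        "ethnicity": "White",
        "marital": "Single",
        "imd_quartile": "Q2",
        "first_contact_date": ["" if i in missing else "2012-06-01" for i in range(n_identified)],
        "age_at_first_presentation": 35,
    })
    texts = []
    for i in range(n_identified):
        if i in ind:
            texts.append(INDETERMINATE_TEMPLATES[0])
        elif i in exposed:
            texts.append("In today's session she disclosed that she was sexually abused as a child.")
        else:
            texts.append(NEUTRAL_TEMPLATES[i % len(NEUTRAL_TEMPLATES)])
    notes = pd.DataFrame({
        "note_id": [f"N{i:08d}" for i in range(1, n_identified + 1)],
        "patient_id": pids,
        "date": "2013-01-01",
        "text": texts,
    })
    honos = pd.DataFrame(
        [(pid, "2013-06-01", *([0] * len(HONOS_ITEMS))) for pid in pids],
        columns=["patient_id", "date", *HONOS_ITEMS],
    )
    diagnoses = pd.DataFrame({"patient_id": pids, "code": "F20.0"})
    admissions = pd.DataFrame(columns=["patient_id", "start_date", "end_date"])
    truth = pd.DataFrame({
        "note_id": notes["note_id"],
        "patient_id": pids,
        "label": [
            "indeterminate" if i in ind else ("positive" if i in exposed else "none")
            for i in range(n_identified)
        ],
        "true_csa": [i in exposed for i in range(n_identified)],
    })
    return CohortData(registry, notes, honos, admissions, diagnoses, truth)
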