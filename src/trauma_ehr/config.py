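"""Configuration for the synthetic severe-mental-illness EHR cohort.

Defaults emulate the published reference cohort the package's analyses are
modelled on: 7000 patients, 8.8% with a recorded history of childhood
sexual abuse (CSA), whole-cohort demographic marginals taken from the
reference demographic table, and exposure-dependent outcome rates generated
from logistic models whose baselines and log-odds-ratios reproduce the
reference outcome table.  Where the reference report prints no value (HoNOS
item prevalences, note volumes, dose grids), defaults are fixed at values
realistic for a UK secondary mental-health-care cohort and documented in
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml


class ConfigError(ValueError):
    pass


def _normalize(counts: dict[str, float]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


# Whole-cohort demographic category counts of the reference cohort (n=7000).
_REFERENCE_MARGINAL_COUNTS: dict[str, dict[str, float]] = {
    "sex": {"M": 3833, "F": 3167},
    "ethnicity": {"White": 3873, "Black": 1526, "Asian": 510, "Mixed": 300,
                  "Other": 487, "Unknown": 304},
    "marital": {"Single": 4720, "Married": 790, "Divorced": 738, "Widowed": 197,
                "Unknown": 555},
    "deprivation": {"Q1": 1040, "Q2": 1563, "Q3": 1892, "Q4": 1912, "Unknown": 593},
}

# Per-group category counts (no-CSA column, CSA column) of the same table;
# used only to derive the default log-probability tilts that give the CSA
# group its shifted demographic profile.
_REFERENCE_GROUP_COUNTS: dict[str, dict[str, tuple[float, float]]] = {
    "sex": {"M": (3609, 224), "F": (2772, 395)},
    "ethnicity": {"White": (3462, 411), "Black": (1418, 108), "Asian": (485, 25),
                  "Mixed": (257, 43), "Other": (465, 22), "Unknown": (294, 10)},
    "marital": {"Single": (4244, 476), "Married": (741, 49), "Divorced": (680, 58),
                "Widowed": (189, 8), "Unknown": (527, 28)},
    "deprivation": {"Q1": (957, 83), "Q2": (1418, 145), "Q3": (1718, 174),
                    "Q4": (1729, 183), "Unknown": (559, 34)},
}


def default_demographic_marginals() -> dict[str, dict[str, float]]:
    return {var: _normalize(cnt) for var, cnt in _REFERENCE_MARGINAL_COUNTS.items()}


def default_exposed_shifts() -> dict[str, dict[str, float]]:
    """Log tilts moving the CSA group's category shares toward the reference
    CSA column: shift = log(share_in_CSA / share_in_noCSA)."""
    shifts: dict[str, dict[str, float]] = {}
    for var, cats in _REFERENCE_GROUP_COUNTS.items():
        n0 = sum(v[0] for v in cats.values())
        n1 = sum(v[1] for v in cats.values())
        shifts[var] = {
            c: math.log((v[1] / n1) / (v[0] / n0)) for c, v in cats.items()
        }
    return shifts


@dataclass
class OutcomeEffect:
    """One binary outcome's generating logistic model: rate in the unexposed
    group and the log-odds-ratio for CSA exposure."""

    baseline_rate: float
    log_or: float

    def __post_init__(self) -> None:
        if not 0 < self.baseline_rate < 1:
            raise ConfigError(f"baseline_rate {self.baseline_rate} not in (0,1)")


def default_outcome_effects() -> dict[str, OutcomeEffect]:
    # admission / antipsychotic / comorbidity baselines and ORs follow the
    # reference outcome and comorbidity tables; HoNOS item values are
    # package defaults (the reference figure prints no numbers).
    return {
        "admission": OutcomeEffect(0.511, math.log(1.95)),
        "antipsychotic": OutcomeEffect(0.895, math.log(2.48)),
        "mdd": OutcomeEffect(0.076, math.log(1.878)),
        "ptsd": OutcomeEffect(0.014, math.log(3.47)),
        "pd": OutcomeEffect(0.058, math.log(4.58)),
        "substance_misuse": OutcomeEffect(0.30, 0.5),
        "self_harm": OutcomeEffect(0.20, 0.6),
        "depressed_mood": OutcomeEffect(0.40, 0.5),
        "hallucinations_delusions": OutcomeEffect(0.55, 0.4),
        "aggression": OutcomeEffect(0.30, 0.4),
        "relationships": OutcomeEffect(0.50, 0.4),
        "living_conditions": OutcomeEffect(0.30, 0.4),
    }


@dataclass
class DistractorRates:
    """Per-note probabilities (in unexposed patients) of abuse-related
    sentences that must NOT count as childhood-abuse evidence."""

    negated: float = 0.04
    uncertain: float = 0.02
    adult_onset: float = 0.015


@dataclass
class MedParams:
    """Medication-sentence generation: which drugs appear, how often a note
    carries a medication sentence, and how doses sit relative to each drug's
    maximum recommended daily dose."""

    drug_weights: dict[str, float] = field(default_factory=lambda: {
        "olanzapine": 0.30, "risperidone": 0.20, "quetiapine": 0.15,
        "aripiprazole": 0.12, "haloperidol": 0.08, "clozapine": 0.08,
        "amisulpride": 0.05, "chlorpromazine": 0.02,
    })
    med_sentence_rate: float = 0.35   # P(note of a receiving patient has a med sentence)
    dose_present_rate: float = 0.80   # P(med sentence states a dose)
    dose_error_rate: float = 0.01     # P(dosed sentence is a >200%-of-max entry error)
    fraction_mu: float = 0.75         # patient-level dose / max-dose propensity
    fraction_sd: float = 0.35
    exposed_fraction_shift: float = 0.12


@dataclass
class CohortConfig:
    n_patients: int = 7000
    csa_prevalence: float = 0.088
    demographic_marginals: dict[str, dict[str, float]] = field(
        default_factory=default_demographic_marginals
    )
    exposed_shifts: dict[str, dict[str, float]] = field(
        default_factory=default_exposed_shifts
    )
    outcome_effects: dict[str, OutcomeEffect] = field(
        default_factory=default_outcome_effects
    )
    note_rate: float = 2.0            # mean notes per patient-year
    distractor_rates: DistractorRates = field(default_factory=DistractorRates)
    med_params: MedParams = field(default_factory=MedParams)
    indeterminate_rate: float = 0.002  # patients whose only mention is age-indeterminate
    missing_first_contact_rate: float = 0.0
    days_per_year_log_median: float = math.log(10.0)  # admitted patients
    days_per_year_log_sd: float = 1.0
    days_per_year_exposed_shift: float = 0.28
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name, p in [
            ("csa_prevalence", self.csa_prevalence),
            ("indeterminate_rate", self.indeterminate_rate),
            ("missing_first_contact_rate", self.missing_first_contact_rate),
            ("negated", self.distractor_rates.negated),
            ("uncertain", self.distractor_rates.uncertain),
            ("adult_onset", self.distractor_rates.adult_onset),
        ]:
            if not 0 <= p <= 1:
                raise ConfigError(f"{name}={p} is not a probability")
        for var, marg in self.demographic_marginals.items():
            if not marg:
                raise ConfigError(f"empty marginal map for {var}")
            if any(not 0 <= p <= 1 for p in marg.values()):
                raise ConfigError(f"marginal probabilities for {var} outside [0,1]")
            if abs(sum(marg.values()) - 1.0) > 1e-9:
                raise ConfigError(f"marginals for {var} do not sum to 1")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "outcome_effects" in doc:
            doc["outcome_effects"] = {
                k: OutcomeEffect(**v) for k, v in doc["outcome_effects"].items()
            }
        if "distractor_rates" in doc:
            doc["distractor_rates"] = DistractorRates(**doc["distractor_rates"])
        if "med_params" in doc:
            doc["med_params"] = MedParams(**doc["med_params"])
        return cls(**doc)
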