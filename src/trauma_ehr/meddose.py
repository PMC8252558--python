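"""Antipsychotic mention and dose extraction from clinical free text.

A simplified gazetteer-plus-rules extractor: drug names (generic or
commercial) are matched case-insensitively; a dose is read from ``<number>
mg`` patterns in the same sentence, with od/bd/tds frequency tokens
multiplying to a daily dose (unstated frequency defaults to once daily).
Each dosed mention is expressed as a percentage of the drug's maximum
recommended daily dose; values above 200% are flagged as data-entry /
extraction errors and excluded from the per-patient maximum.
"""

from __future__ import annotations

import functools
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

#: percentage of the maximum recommended dose above which a record is
#: treated as a data-quality error and excluded
EXCLUSION_THRESHOLD_PCT = 200.0

_FREQ_MULTIPLIER = {"od": 1, "bd": 2, "tds": 3, "qds": 4}

_SENTENCE_SPLIT = re.compile(r"[.;!?\n]")
_DOSE_RE = re.compile(r"\b(\d+(?:\.\d+)?)\s*mg\b(?:\s+(od|bd|tds|qds)\b)?", re.I)


class GazetteerError(ValueError):
    pass


@dataclass(frozen=True)
class DrugEntry:
    """A gazetteer drug: generic name, commercial synonyms, and the maximum
    recommended daily dose in mg (``None`` for depot formulations, which have
    no daily-dose semantics)."""

    generic_name: str
    synonyms: tuple[str, ...] = ()
    max_daily_dose_mg: float | None = None

    def __post_init__(self) -> None:
        if self.max_daily_dose_mg is not None and self.max_daily_dose_mg <= 0:
            raise GazetteerError(f"{self.generic_name}: max dose must be > 0")


@dataclass
class DoseRecord:
    patient_id: str
    note_id: str
    generic_name: str
    daily_dose_mg: float | None
    pct_max: float | None
    excluded: bool


@dataclass
class DoseSummary:
    patient_id: str
    any_antipsychotic: bool
    max_pct: float | None


def load_gazetteer(path: str | None = None) -> list[DrugEntry]:
    """Load the drug gazetteer from YAML; default to the shipped table."""
    if path is None:
        text = (
            resources.files("trauma_ehr.data").joinpath("antipsychotics.yml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    entries = [
        DrugEntry(
            generic_name=str(row["generic"]).lower(),
            synonyms=tuple(str(s).lower() for s in row.get("synonyms", [])),
            max_daily_dose_mg=(
                float(row["max_daily_mg"]) if row.get("max_daily_mg") is not None else None
            ),
        )
        for row in doc["drugs"]
    ]
    names: set[str] = set()
    for e in entries:
        for name in (e.generic_name, *e.synonyms):
            if name in names:
                raise GazetteerError(f"duplicate drug name {name!r}")
            names.add(name)
    if not entries:
        raise GazetteerError("gazetteer is empty")
    return entries


def compute_pct_max(daily_dose_mg: float, max_daily_dose_mg: float) -> tuple[float, bool]:
    """Percentage of the maximum recommended daily dose, with exclusion flag.

    Records above 200% of the maximum are flagged for exclusion as probable
    dosage-entry or extraction errors.
    """
    if daily_dose_mg <= 0 or max_daily_dose_mg <= 0:
        raise ValueError("doses must be positive")
    pct = 100.0 * daily_dose_mg / max_daily_dose_mg
    return pct, pct > EXCLUSION_THRESHOLD_PCT


@functools.lru_cache(maxsize=None)
def _name_regex(entry: DrugEntry) -> re.Pattern:
    alts = sorted((entry.generic_name, *entry.synonyms), key=len, reverse=True)
    return re.compile(r"(?<!\w)(" + "|".join(re.escape(a) for a in alts) + r")(?!\w)", re.I)


def extract_medication_mentions(
    note_id: str,
    patient_id: str,
    text: str,
    gazetteer: Sequence[DrugEntry],
) -> list[DoseRecord]:
    """Find antipsychotic mentions and any same-sentence dose.

    One record per drug per sentence; the first dose pattern after the drug
    name (falling back to the first in the sentence) is used.  A mention
    without a parseable dose — including any depot formulation — yields
    ``daily_dose_mg=None`` and still counts as antipsychotic receipt.
    """
    records: list[DoseRecord] = []
    for sentence in _SENTENCE_SPLIT.split(text):
        if not sentence.strip():
            continue
        doses = list(_DOSE_RE.finditer(sentence))
        for entry in gazetteer:
            m = _name_regex(entry).search(sentence)
            if m is None:
                continue
            dose_m = next((d for d in doses if d.start() >= m.end()), doses[0] if doses else None)
            daily = pct = None
            excluded = False
            if dose_m is not None and entry.max_daily_dose_mg is not None:
                per_admin = float(dose_m.group(1))
                freq = _FREQ_MULTIPLIER.get((dose_m.group(2) or "od").lower(), 1)
                daily = per_admin * freq
                pct, excluded = compute_pct_max(daily, entry.max_daily_dose_mg)
            records.append(
                DoseRecord(
                    patient_id=patient_id,
                    note_id=note_id,
                    generic_name=entry.generic_name,
                    daily_dose_mg=daily,
                    pct_max=pct,
                    excluded=excluded,
                )
            )
    return records


def summarize_patient_dosing(patient_id: str, records: Iterable[DoseRecord]) -> DoseSummary:
    """Per-patient roll-up: any mention at all, and the highest non-excluded
    percentage of maximum recommended daily dose."""
    records = list(records)
    if any(r.patient_id != patient_id for r in records):
        raise ValueError("records belong to multiple patients")
    usable = [r.pct_max for r in records if r.pct_max is not None and not r.excluded]
    return DoseSummary(
        patient_id=patient_id,
        any_antipsychotic=bool(records),
        max_pct=max(usable) if usable else None,
    )


def dichotomize_at_median(values: Sequence[float]) -> tuple[float, list[bool]]:
    """Empirical median split; the "above" flag is strict (ties sit below).

    Used for both admission days per year and dose percentages; for even n
    the median is the mean of the middle pair.
    """
    vals = [float(v) for v in values]
    if not vals or any(math.isnan(v) for v in vals):
        raise ValueError("need at least one non-NaN value")
    med = float(np.median(vals))
    return med, [v > med for v in vals]
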