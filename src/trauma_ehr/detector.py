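"""Rule-based detection of recorded childhood sexual abuse in clinical notes.

The detector normalizes note text, finds all lexicon phrases, resolves
overlaps under a fixed precedence (exclusion and indeterminate phrases beat
inclusion phrases; longer matches beat shorter ones), and rolls note-level
spans up to a patient-level exposure status:

* ``exposed`` — at least one effective include span whose extracted ages (if
  any) are all below the childhood cutoff;
* ``removed_indeterminate`` — no such span, but at least one indeterminate
  mention (abuse recorded without a confirmable age); these patients are
  dropped from the analytic cohort entirely;
* ``unexposed`` — anything else, including include phrases whose extracted
  age is at or above the cutoff (adult abuse).

A note-level flag (:func:`flag_note`) supports the positive-predictive-value
audit: a note is "flagged" when it on its own provides childhood-abuse
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .lexicon import CompiledEntry, LexiconEntry, compile_lexicon

#: Age (in completed years) below which an extracted age counts as childhood.
DEFAULT_CHILDHOOD_CUTOFF = 18

EXPOSED = "exposed"
UNEXPOSED = "unexposed"
REMOVED = "removed_indeterminate"

# Polarity rank used in overlap resolution: blocking phrases are placed first.
_POLARITY_RANK = {"exclude": 0, "indeterminate": 0, "include": 1}


def normalize_text(text: str) -> tuple[str, list[tuple[int, int]]]:
    """Case-fold and collapse whitespace, keeping a map back to raw offsets.

    Returns ``(normalized, spans)`` where ``spans[i] = (raw_start, raw_end)``
    is the half-open raw-text span that produced normalized character ``i``.
    Leading/trailing whitespace is dropped; interior whitespace runs collapse
    to a single space mapped to the whole run they replace.
    """
    out: list[str] = []
    spans: list[tuple[int, int]] = []
    ws_start: int | None = None
    for i, ch in enumerate(text):
        if ch.isspace():
            if ws_start is None:
                ws_start = i
            continue
        if ws_start is not None:
            if out:  # interior run -> one space; leading run -> dropped
                out.append(" ")
                spans.append((ws_start, i))
            ws_start = None
        low = ch.lower()
        for c in low:  # rare one-to-many case folds map to the same raw char
            out.append(c)
            spans.append((i, i + 1))
    return "".join(out), spans


def to_raw_span(spans: list[tuple[int, int]], start: int, end: int) -> tuple[int, int]:
    """Map a half-open span on normalized text back to raw-text offsets."""
    if start >= end:
        raise ValueError("empty span")
    return spans[start][0], spans[end - 1][1]


@dataclass(frozen=True)
class MatchSpan:
    """A lexicon hit on one note; offsets are 0-based half-open on raw text."""

    note_id: str
    start: int
    end: int
    pattern_id: str
    polarity: str
    extracted_ages: tuple[int, ...] = ()


@dataclass
class ExposureLabel:
    patient_id: str
    status: str
    evidence: list[MatchSpan] = field(default_factory=list)


def scan_note(
    note_id: str,
    text: str,
    compiled: list[CompiledEntry],
) -> list[MatchSpan]:
    """Find all non-overlapping lexicon matches in one note.

    Candidates from every pattern are pooled and selected greedily under the
    precedence (blocking polarity first, then longer match, then earlier
    start); a candidate overlapping an already-selected span is suppressed.
    This is what makes ``"nil csa"`` block the embedded ``"csa"``.
    """
    norm, offmap = normalize_text(text)
    candidates: list[tuple[int, int, int, int, CompiledEntry, tuple[int, ...]]] = []
    for ce in compiled:
        for m in ce.regex.finditer(norm):
            ages = tuple(int(g) for g in m.groups() if g is not None)
            key = (_POLARITY_RANK[ce.entry.polarity], m.start() - m.end(), m.start())
            candidates.append((*key, 0, ce, (m.start(), m.end()) + (ages,)))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[4].entry.pattern_id))

    taken: list[tuple[int, int]] = []
    result: list[MatchSpan] = []
    for _, _, _, _, ce, payload in candidates:
        start, end, ages = payload
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        raw_start, raw_end = to_raw_span(offmap, start, end)
        result.append(
            MatchSpan(
                note_id=note_id,
                start=raw_start,
                end=raw_end,
                pattern_id=ce.entry.pattern_id,
                polarity=ce.entry.polarity,
                extracted_ages=ages,
            )
        )
    result.sort(key=lambda s: s.start)
    return result


def _is_childhood_evidence(span: MatchSpan, cutoff: int) -> bool:
    """An include span is evidence unless any extracted age is >= cutoff."""
    if span.polarity != "include":
        return False
    return all(a < cutoff for a in span.extracted_ages)


def flag_note(spans: list[MatchSpan], cutoff: int = DEFAULT_CHILDHOOD_CUTOFF) -> bool:
    """True when the note provides childhood-abuse evidence on its own."""
    return any(_is_childhood_evidence(s, cutoff) for s in spans)


def classify_patient(
    patient_id: str,
    spans: list[MatchSpan],
    cutoff: int = DEFAULT_CHILDHOOD_CUTOFF,
) -> ExposureLabel:
    """Roll all of one patient's match spans up to an exposure status.

    Any effective include span dominates: a negated mention in one note does
    not override a positive mention in another.  Include spans carrying an
    adult age are demoted to non-evidence rather than treated as blocking.
    """
    evidence = [s for s in spans if _is_childhood_evidence(s, cutoff)]
    if evidence:
        return ExposureLabel(patient_id, EXPOSED, evidence)
    indeterminate = [s for s in spans if s.polarity == "indeterminate"]
    if indeterminate:
        return ExposureLabel(patient_id, REMOVED, indeterminate)
    return ExposureLabel(patient_id, UNEXPOSED, [])


class Detector:
    """Convenience wrapper binding a compiled lexicon and childhood cutoff."""

    def __init__(
        self,
        lexicon: list[LexiconEntry],
        cutoff: int = DEFAULT_CHILDHOOD_CUTOFF,
    ):
        self.lexicon = lexicon
        self.compiled = compile_lexicon(lexicon)
        self.cutoff = cutoff
        # one cheap alternation pass rejects the (typical) note with no
        # lexicon phrase before the per-pattern scan runs
        import re as _re

        self._any = _re.compile("|".join(f"(?:{c.regex.pattern})" for c in self.compiled))

    def scan(self, note_id: str, text: str) -> list[MatchSpan]:
        norm, _ = normalize_text(text)
        if self._any.search(norm) is None:
            return []
        return scan_note(note_id, text, self.compiled)

    def classify(self, patient_id: str, spans: list[MatchSpan]) -> ExposureLabel:
        return classify_patient(patient_id, spans, self.cutoff)


class EmptyAuditError(ValueError):
    """Raised when a PPV audit is requested but no notes were flagged."""


def ppv_audit(
    flagged_note_ids: list[str],
    truth_positive: set[str],
    sample_size: int,
    seed: int,
) -> tuple[float, tuple[float, float], int]:
    """Audit a random sample of flagged notes against ground truth.

    Mirrors a manual chart review: sample ``sample_size`` flagged notes
    uniformly without replacement and count how many are genuine positives.
    Returns ``(ppv, (ci_low, ci_high), n_true)`` with an exact
    Clopper–Pearson 95% interval.
    """
    if not flagged_note_ids:
        raise EmptyAuditError("no flagged notes to audit")
    if sample_size > len(flagged_note_ids):
        raise ValueError(
            f"sample_size {sample_size} exceeds {len(flagged_note_ids)} flagged notes"
        )
    rng = np.random.default_rng(seed)
    sample = rng.choice(np.asarray(flagged_note_ids, dtype=object), size=sample_size, replace=False)
    n_true = sum(1 for nid in sample if nid in truth_positive)
    ppv = n_true / sample_size
    low, high = proportion_confint(n_true, sample_size, alpha=0.05, method="beta")
    return ppv, (float(low), float(high)), n_true
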