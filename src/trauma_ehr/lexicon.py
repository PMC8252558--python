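"""CSA string-matching lexicon: loading, validation and compilation.

A lexicon is a flat list of literal phrases (optionally carrying ``{age}``
slots) with a polarity that drives the matching precedence in
:mod:`trauma_ehr.detector`:

* ``include`` — asserts a recorded history of childhood sexual abuse;
* ``exclude`` — negates the history or marks it as merely possible, and
  blocks any include phrase it overlaps;
* ``indeterminate`` — abuse recorded without a confirmable age at the time
  of the abuse; patients whose only evidence is indeterminate are removed
  from the analytic cohort rather than classified.

Phrases are matched literally after normalization (no stemming, no spelling
correction): the detector is a string matcher, not a statistical NLP model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml

POLARITIES = ("include", "exclude", "indeterminate")

AGE_SLOT = "{age}"
_AGE_GROUP = r"(\d{1,2})"


class LexiconError(ValueError):
    """Raised when a lexicon file is malformed."""


@dataclass(frozen=True)
class LexiconEntry:
    """One phrase of the matching lexicon.

    ``surface`` is the literal phrase on normalized text; ``{age}`` marks a
    1–2 digit age slot (a range template simply contains two slots).
    """

    pattern_id: str
    surface: str
    polarity: str
    notes: str = ""

    @property
    def n_age_slots(self) -> int:
        return self.surface.count(AGE_SLOT)

    def __post_init__(self) -> None:
        if not self.pattern_id:
            raise LexiconError("pattern_id must be non-empty")
        if not self.surface or not self.surface.strip():
            raise LexiconError(f"{self.pattern_id}: surface must be non-empty")
        if self.polarity not in POLARITIES:
            raise LexiconError(
                f"{self.pattern_id}: polarity {self.polarity!r} not one of {POLARITIES}"
            )
        leftover = re.sub(re.escape(AGE_SLOT), "", self.surface)
        if "{" in leftover or "}" in leftover:
            raise LexiconError(
                f"{self.pattern_id}: malformed template {self.surface!r}; "
                f"only {AGE_SLOT!r} slots are allowed"
            )


@dataclass
class CompiledEntry:
    """A lexicon entry compiled to a word-boundary-aware regex."""

    entry: LexiconEntry
    regex: re.Pattern = field(repr=False)


def compile_entry(entry: LexiconEntry) -> CompiledEntry:
    """Compile a surface to a regex over normalized text.

    Literal parts are escaped; age slots become capturing ``(\\d{1,2})``
    groups.  Word boundaries are enforced at each end of the phrase only when
    the phrase actually starts/ends with a word character, so punctuation-led
    surfaces like ``"? csa"`` still match.
    """
    parts = entry.surface.split(AGE_SLOT)
    pattern = _AGE_GROUP.join(re.escape(p) for p in parts)
    if entry.surface[0].isalnum() or entry.surface[0] == "_" or parts[0] == "":
        pattern = r"(?<!\w)" + pattern
    if entry.surface[-1].isalnum() or entry.surface[-1] == "_" or parts[-1] == "":
        pattern = pattern + r"(?!\w)"
    return CompiledEntry(entry=entry, regex=re.compile(pattern))


def validate_lexicon(entries: Iterable[LexiconEntry]) -> list[LexiconEntry]:
    entries = list(entries)
    if not entries:
        raise LexiconError("lexicon is empty")
    seen: set[str] = set()
    for e in entries:
        if e.pattern_id in seen:
            raise LexiconError(f"duplicate pattern_id {e.pattern_id!r}")
        seen.add(e.pattern_id)
    return entries


def load_lexicon(path: str | None = None) -> list[LexiconEntry]:
    """Load a lexicon from YAML; with ``path=None`` load the shipped default."""
    if path is None:
        text = (
            resources.files("trauma_ehr.data").joinpath("lexicon.yml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "entries" not in doc:
        raise LexiconError("lexicon file must contain an 'entries' list")
    entries = [
        LexiconEntry(
            pattern_id=str(row["pattern_id"]),
            surface=str(row["surface"]),
            polarity=str(row["polarity"]),
            notes=str(row.get("notes", "")),
        )
        for row in doc["entries"]
    ]
    return validate_lexicon(entries)


def compile_lexicon(entries: Iterable[LexiconEntry]) -> list[CompiledEntry]:
    return [compile_entry(e) for e in validate_lexicon(entries)]
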