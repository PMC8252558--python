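"""Reading and writing the cohort table bundle.

Registry, HoNOS, admissions, diagnoses and truth travel as CSV with
ISO-8601 dates; notes travel as JSON-lines with one object per note
(``note_id``, ``patient_id``, ``date``, ``text``).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthetic import CohortData

_CSV_TABLES = ("registry", "honos", "admissions", "diagnoses", "truth")


def write_notes_jsonl(notes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in notes.itertuples(index=False):
            fh.write(json.dumps(row._asdict(), ensure_ascii=False) + "\n")


def read_notes_jsonl(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        rows = [json.loads(line) for line in fh if line.strip()]
    return pd.DataFrame(rows, columns=["note_id", "patient_id", "date", "text"])


def write_cohort(data: CohortData, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _CSV_TABLES:
        getattr(data, name).to_csv(out / f"{name}.csv", index=False)
    write_notes_jsonl(data.notes, out / "notes.jsonl")


def read_cohort(indir: str | Path) -> CohortData:
    ind = Path(indir)
    tables = {
        name: pd.read_csv(ind / f"{name}.csv", keep_default_na=False, dtype={"patient_id": str})
        for name in _CSV_TABLES
    }
    if "true_csa" in tables["truth"].columns:
        tables["truth"]["true_csa"] = tables["truth"]["true_csa"].astype(str).str.lower().isin(
            ["true", "1"]
        )
    return CohortData(notes=read_notes_jsonl(ind / "notes.jsonl"), **tables)
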