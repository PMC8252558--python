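"""End-to-end orchestration: simulate → detect → doses → features → analyze.

The pipeline mirrors a retrospective EHR cohort study.  Patients are
identified from the registry (severe-mental-illness diagnosis, contact in
the study window with a year of follow-up, at least one HoNOS assessment),
then removed when follow-up cannot be computed (missing first-contact date)
or when their only abuse mention is age-indeterminate; the remainder form
the analytic cohort, split by detected CSA exposure.  The analysis stage
emits four report tables — demographics, comorbidities, HoNOS prevalence by
group, and clinical outcomes with unadjusted and covariate-adjusted odds
ratios — plus a machine-readable JSON of every effect estimate and a run
manifest (config snapshot, seeds, input digests, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import CohortConfig
from .detector import Detector, EXPOSED, REMOVED, flag_note, ppv_audit
from .features import (
    ANALYSIS_ITEMS,
    STUDY_WINDOW,
    comorbidity_flags,
    derive_admission_outcomes,
    dichotomize_honos,
    filter_cohort,
    follow_up_years,
    honos_prevalence_by_group,
)
from .io import write_cohort
from .lexicon import load_lexicon
from .meddose import (
    dichotomize_at_median,
    extract_medication_mentions,
    load_gazetteer,
    summarize_patient_dosing,
)
from .stats import (
    EffectEstimate,
    build_table,
    fit_logistic,
    odds_ratio_2x2,
    odds_ratio_from_proportions,
    pearson_chi_square,
)
from .synthetic import CohortData, generate_cohort

log = logging.getLogger("trauma_ehr")

ADJUSTMENT_COVARIATES = ["sex", "age_at_first_presentation", "ethnicity"]


@dataclass
class CohortFlow:
    """Stage-by-stage patient accounting, echoing the study flow."""

    n_identified: int
    n_missing_first_contact: int
    n_removed_indeterminate: int
    n_analytic: int
    n_exposed: int

    @property
    def detected_prevalence(self) -> float:
        return self.n_exposed / self.n_analytic


def detect_exposure(notes: pd.DataFrame, detector: Detector) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan all notes; return patient labels and note-level flags.

    Patient labels carry status in {exposed, unexposed,
    removed_indeterminate}; note flags mark notes that on their own provide
    childhood-abuse evidence (the unit of the PPV audit).
    """
    spans_by_patient: dict[str, list] = {}
    flag_rows = []
    for row in notes.itertuples(index=False):
        spans = detector.scan(row.note_id, row.text)
        spans_by_patient.setdefault(row.patient_id, []).extend(spans)
        if flag_note(spans, detector.cutoff):
            flag_rows.append(row.note_id)
    labels = pd.DataFrame(
        [
            (pid, detector.classify(pid, spans).status)
            for pid, spans in spans_by_patient.items()
        ],
        columns=["patient_id", "status"],
    )
    flagged = pd.DataFrame({"note_id": flag_rows})
    return labels, flagged


def cohort_flow(
    registry: pd.DataFrame,
    honos: pd.DataFrame,
    diagnoses: pd.DataFrame,
    labels: pd.DataFrame,
    window: tuple[date, date] = STUDY_WINDOW,
) -> tuple[CohortFlow, pd.DataFrame]:
    """Apply eligibility and removal rules; return flow counts and the
    analytic cohort (registry rows plus a boolean ``csa`` column)."""
    n_identified = len(registry)
    has_fc = registry["first_contact_date"].astype(str).str.len() > 0
    n_missing = int((~has_fc).sum())
    eligible = filter_cohort(registry[has_fc], honos, diagnoses, window)

    status = labels.set_index("patient_id")["status"]
    st = eligible["patient_id"].map(status).fillna("unexposed")
    removed = st == REMOVED
    n_removed = int(removed.sum())
    analytic = eligible[~removed.to_numpy()].copy()
    analytic["csa"] = (st[~removed.to_numpy()] == EXPOSED).to_numpy()
    flow = CohortFlow(
        n_identified=n_identified,
        n_missing_first_contact=n_missing,
        n_removed_indeterminate=n_removed,
        n_analytic=len(analytic),
        n_exposed=int(analytic["csa"].sum()),
    )
    log.info(
        "cohort flow: %d identified -> -%d missing first contact -> -%d "
        "indeterminate age -> %d analytic (%d exposed, %.1f%%)",
        flow.n_identified, flow.n_missing_first_contact, flow.n_removed_indeterminate,
        flow.n_analytic, flow.n_exposed, 100 * flow.detected_prevalence,
    )
    return flow, analytic


def derive_feature_frame(
    analytic: pd.DataFrame,
    data: CohortData,
    honos_threshold: int = 3,
) -> pd.DataFrame:
    """Patient-level analysis frame: demographics, exposure, HoNOS flags,
    comorbidities, admission outcomes and dose summaries."""
    df = analytic.set_index("patient_id")
    ids = df.index

    honos = data.honos[data.honos["patient_id"].isin(ids)]
    hflags = dichotomize_honos(honos, threshold=honos_threshold).reindex(ids, fill_value=False)

    codes = data.diagnoses.groupby("patient_id")["code"].apply(list)
    cflags = pd.DataFrame(
        [comorbidity_flags(codes.get(pid, [])) for pid in ids], index=ids
    )

    fc = pd.to_datetime(df["first_contact_date"]).dt.date
    fup = fc.map(follow_up_years)

    adm = data.admissions[data.admissions["patient_id"].isin(ids)]
    eps = {
        pid: list(zip(pd.to_datetime(g["start_date"]).dt.date, pd.to_datetime(g["end_date"]).dt.date))
        for pid, g in adm.groupby("patient_id")
    }
    adm_out = {
        pid: derive_admission_outcomes(eps.get(pid, []), max(fup[pid], 1.0)) for pid in ids
    }

    gazetteer = load_gazetteer()
    dose_records: dict[str, list] = {pid: [] for pid in ids}
    for row in data.notes.itertuples(index=False):
        if row.patient_id in dose_records:
            dose_records[row.patient_id].extend(
                extract_medication_mentions(row.note_id, row.patient_id, row.text, gazetteer)
            )
    dose_sum = {pid: summarize_patient_dosing(pid, recs) for pid, recs in dose_records.items()}

    out = pd.DataFrame({
        "csa": df["csa"].astype(bool),
        "sex": df["sex"],
        "ethnicity": df["ethnicity"],
        "marital": df["marital"],
        "imd_quartile": df["imd_quartile"],
        "age_at_first_presentation": df["age_at_first_presentation"].astype(float),
        "follow_up_years": fup,
        "any_admission": [adm_out[p].any_admission for p in ids],
        "admission_days_per_year": [adm_out[p].days_per_year for p in ids],
        "any_antipsychotic": [dose_sum[p].any_antipsychotic for p in ids],
        "max_dose_pct": [dose_sum[p].max_pct for p in ids],
    })
    return pd.concat([out, hflags.add_prefix("honos_"), cflags], axis=1)


def _estimate_to_dict(name: str, est: EffectEstimate) -> dict:
    d = dataclasses.asdict(est)
    d["name"] = name
    return d


def analyze_cohort(features: pd.DataFrame, drop_unknown: bool = False) -> dict:
    """The statistical layer of the study on a derived feature frame.

    Returns a dict of report tables (DataFrames) and effect estimates.
    Chi-square tests are uncorrected Pearson with Unknown categories
    retained (toggleable); outcome odds ratios come unadjusted (2×2) and
    adjusted for sex, age at first presentation and ethnicity (logistic).
    """
    estimates: list[dict] = []

    demo_rows = []
    for var, col in [("sex", "sex"), ("ethnicity", "ethnicity"),
                     ("marital", "marital"), ("deprivation", "imd_quartile")]:
        tab = build_table(features.reset_index(), col, "csa", drop_unknown=drop_unknown)
        chi = pearson_chi_square(tab)
        estimates.append(_estimate_to_dict(f"chi2_{var}", chi))
        for lab, row in zip(tab.row_labels, tab.counts):
            demo_rows.append((var, lab, row[0], row[1], round(chi.point, 2), chi.p_value))
    demographics = pd.DataFrame(
        demo_rows, columns=["variable", "category", "no_csa", "csa", "chi_square", "p_value"]
    )

    com_rows = []
    for var in ("mdd", "ptsd", "pd"):
        tab = build_table(features.reset_index(), var, "csa")
        chi = pearson_chi_square(tab)
        estimates.append(_estimate_to_dict(f"chi2_{var}", chi))
        for lab, row in zip(tab.row_labels, tab.counts):
            com_rows.append((var, lab, row[0], row[1], round(chi.point, 2), chi.p_value))
    comorbidity = pd.DataFrame(
        com_rows, columns=["variable", "category", "no_csa", "csa", "chi_square", "p_value"]
    )

    honos_prev = honos_prevalence_by_group(
        features[[f"honos_{i}" for i in ANALYSIS_ITEMS]].rename(
            columns=lambda c: c.removeprefix("honos_")
        ),
        features["csa"],
    )

    outcome_rows = []
    specs: list[tuple[str, pd.DataFrame, pd.Series]] = [
        ("admission", features, features["any_admission"]),
        ("antipsychotic", features, features["any_antipsychotic"]),
    ]
    admitted = features[features["any_admission"]]
    if len(admitted):
        _, above = dichotomize_at_median(admitted["admission_days_per_year"])
        specs.append(("days_above_median", admitted, pd.Series(above, index=admitted.index)))
    dosed = features[features["max_dose_pct"].notna()]
    if len(dosed):
        _, above = dichotomize_at_median(dosed["max_dose_pct"])
        specs.append(("dose_above_median", dosed, pd.Series(above, index=dosed.index)))

    for name, frame, outcome in specs:
        sub = frame.assign(outcome=outcome.astype(bool))
        a = int(((~sub["csa"]) & ~sub["outcome"]).sum())
        b = int(((~sub["csa"]) & sub["outcome"]).sum())
        c = int((sub["csa"] & ~sub["outcome"]).sum())
        d = int((sub["csa"] & sub["outcome"]).sum())
        crude = odds_ratio_2x2(a, b, c, d)
        adj = fit_logistic(sub, "outcome", "csa", ADJUSTMENT_COVARIATES)
        estimates.append(_estimate_to_dict(f"or_{name}", crude))
        estimates.append(_estimate_to_dict(f"adj_or_{name}", adj))
        outcome_rows.append((
            name,
            round(100 * b / (a + b), 1), round(100 * d / (c + d), 1),
            round(crude.point, 2), round(crude.ci_low, 2), round(crude.ci_high, 2),
            round(adj.point, 2), round(adj.ci_low, 2), round(adj.ci_high, 2),
        ))
    outcomes = pd.DataFrame(outcome_rows, columns=[
        "outcome", "pct_no_csa", "pct_csa", "or", "or_low", "or_high",
        "adj_or", "adj_or_low", "adj_or_high",
    ])

    return {
        "demographics": demographics,
        "comorbidity": comorbidity,
        "honos_prevalence": honos_prev.reset_index(),
        "outcomes": outcomes,
        "estimates": estimates,
    }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    lexicon_version: int
    input_digests: dict[str, str] = field(default_factory=dict)
    software_version: str = __version__
    timestamp: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")


def run_pipeline(
    config: CohortConfig,
    outdir: str | Path,
    honos_threshold: int = 3,
    drop_unknown: bool = False,
    data: CohortData | None = None,
) -> dict:
    """Full study on a synthetic (or supplied) cohort; writes a report dir.

    Returns the analysis dict augmented with the cohort flow and manifest.
    Deterministic for a fixed config/seed: the report tables are
    byte-identical across reruns (the manifest timestamp is provenance, not
    part of the determinism contract).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if data is None:
        log.info("simulate: generating cohort of %d patients (seed %d)",
                 config.n_patients, config.seed)
        data = generate_cohort(config)
    write_cohort(data, out / "cohort")

    lexicon = load_lexicon()
    detector = Detector(lexicon)
    log.info("detect: scanning %d notes", len(data.notes))
    labels, flagged = detect_exposure(data.notes, detector)
    flow, analytic = cohort_flow(data.registry, data.honos, data.diagnoses, labels)
    log.info("features: deriving outcomes for %d patients", len(analytic))
    features = derive_feature_frame(analytic, data, honos_threshold)
    log.info("analyze: %d exposed vs %d unexposed",
             flow.n_exposed, flow.n_analytic - flow.n_exposed)
    result = analyze_cohort(features, drop_unknown=drop_unknown)

    for name in ("demographics", "comorbidity", "honos_prevalence", "outcomes"):
        result[name].to_csv(out / f"table_{name}.csv", index=False)
    labels.to_csv(out / "labels.csv", index=False)
    features.to_csv(out / "features.csv")
    (out / "estimates.json").write_text(json.dumps(result["estimates"], indent=2) + "\n")

    lex_doc = yaml.safe_load(
        resources.files("trauma_ehr.data").joinpath("lexicon.yml").read_text()
    )
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=config.seed,
        lexicon_version=int(lex_doc.get("version", 0)),
        input_digests={
            p.name: _digest(p) for p in sorted((out / "cohort").iterdir())
        },
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(out / "manifest.json")

    flow_d = dataclasses.asdict(flow)
    flow_d["detected_prevalence"] = flow.detected_prevalence
    (out / "cohort_flow.json").write_text(json.dumps(flow_d, indent=2) + "\n")
    _write_summary(out, flow, result)

    result.update({"flow": flow, "manifest": manifest, "features": features,
                   "labels": labels, "flagged": flagged, "data": data})
    return result


def _write_summary(out: Path, flow: CohortFlow, result: dict) -> None:
    lines = [
        "# Cohort report",
        "",
        f"- patients identified: {flow.n_identified}",
        f"- removed, missing first-contact date: {flow.n_missing_first_contact}",
        f"- removed, indeterminate age at abuse: {flow.n_removed_indeterminate}",
        f"- analytic cohort: {flow.n_analytic}",
        f"- detected CSA exposure: {flow.n_exposed} "
        f"({100 * flow.detected_prevalence:.1f}%)",
        "",
        "## Clinical outcomes (CSA vs no CSA)",
        "",
        result["outcomes"].to_markdown(index=False),
        "",
        "Tables: table_demographics.csv, table_comorbidity.csv, "
        "table_honos_prevalence.csv, table_outcomes.csv; full estimates in "
        "estimates.json; provenance in manifest.json.",
    ]
    (out / "summary.md").write_text("\n".join(lines) + "\n")


def run_ppv_audit(
    notes: pd.DataFrame,
    truth: pd.DataFrame,
    detector: Detector,
    sample_size: int = 100,
    seed: int = 2,
) -> dict:
    """Audit detector-flagged notes against generator truth.

    Emulates a manual chart review of ``sample_size`` randomly drawn flagged
    notes; a note counts as a true positive when its ground-truth label is a
    genuine childhood-abuse mention.
    """
    _, flagged = detect_exposure(notes, detector)
    truth_positive = set(truth.loc[truth["label"] == "positive", "note_id"])
    ppv, ci, n_true = ppv_audit(
        flagged["note_id"].tolist(), truth_positive, sample_size, seed
    )
    return {
        "n_flagged": len(flagged),
        "sample_size": sample_size,
        "n_true_positive": n_true,
        "ppv": ppv,
        "ci_low": ci[0],
        "ci_high": ci[1],
    }


def replay_reference_tables(counts_path: str | None = None) -> pd.DataFrame:
    """Recompute chi-square statistics and odds ratios from published
    summary counts shipped with (or supplied to) the package.

    Each cross-tabulation is re-tested with uncorrected Pearson chi-square
    and compared against the statistic printed alongside the counts; each
    outcome's odds ratio is recomputed from the printed group percentages.
    """
    if counts_path is None:
        doc = yaml.safe_load(
            resources.files("trauma_ehr.data").joinpath("reference_counts.yml").read_text()
        )
    else:
        with open(counts_path) as fh:
            doc = yaml.safe_load(fh)
    rows = []
    for var, spec in doc["tables"].items():
        from .stats import ContingencyTable

        tab = ContingencyTable(
            row_labels=[str(c) for c in spec["categories"]],
            col_labels=["no_csa", "csa"],
            counts=list(map(list, zip(spec["no_csa"], spec["csa"]))),
        )
        chi = pearson_chi_square(tab)
        rows.append({
            "quantity": f"chi2_{var}",
            "recomputed": round(chi.point, 2),
            "published": spec["chi_square_2dp"],
            "p_value": chi.p_value,
        })
    n0, n1 = doc["cohort"]["n_total"] - doc["cohort"]["n_csa"], doc["cohort"]["n_csa"]
    for name, spec in doc.get("outcomes", {}).items():
        est = odds_ratio_from_proportions(
            spec["pct_no_csa"] / 100, spec["pct_csa"] / 100, n0, n1
        )
        rows.append({
            "quantity": f"or_{name}",
            "recomputed": round(est.point, 2),
            "published": spec["printed_or"],
            "p_value": est.p_value,
        })
    return pd.DataFrame(rows)
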