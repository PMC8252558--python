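"""The synthetic cohort generator: determinism, configured prevalences,
ground-truth guarantees, and agreement with the detector's rules."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from trauma_ehr.config import CohortConfig, ConfigError, OutcomeEffect
from trauma_ehr.detector import flag_note
from trauma_ehr.io import read_cohort, write_cohort
from trauma_ehr.synthetic import (
    conditional_category_probs,
    generate_cohort,
    generate_note_text,
    sample_binary_outcomes,
)


class TestConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(csa_prevalence=1.5)

    def test_marginals_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            CohortConfig(demographic_marginals={"sex": {"M": 0.7, "F": 0.7}})

    def test_empty_marginal_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(demographic_marginals={"sex": {}})

    def test_yaml_roundtrip(self, tmp_path):
        cfg = dataclasses.replace(CohortConfig(), n_patients=12, seed=3)
        path = tmp_path / "cohort.yml"
        cfg.to_yaml(str(path))
        assert CohortConfig.from_yaml(str(path)) == cfg


class TestGenerateCohort:
    def test_registry_size_and_structure(self, small_cohort, small_config):
        assert len(small_cohort.registry) == small_config.n_patients
        assert small_cohort.honos.groupby("patient_id").size().min() >= 1
        # every first contact leaves at least a year of follow-up
        fc = pd.to_datetime(small_cohort.registry["first_contact_date"])
        assert ((pd.Timestamp("2017-12-31") - fc).dt.days >= 365).all()

    def test_true_prevalence_within_binomial_noise(self):
        cfg = dataclasses.replace(CohortConfig(), n_patients=7000, seed=1)
        data = generate_cohort(cfg)
        n_csa = data.truth.drop_duplicates("patient_id")["true_csa"].sum()
        mean = 7000 * 0.088
        sd = np.sqrt(7000 * 0.088 * 0.912)
        assert abs(n_csa - mean) <= 3 * sd

    def test_zero_prevalence_has_no_positives(self):
        cfg = dataclasses.replace(CohortConfig(), n_patients=10, csa_prevalence=0.0, seed=7)
        data = generate_cohort(cfg)
        assert not data.truth["true_csa"].any()
        assert (data.truth["label"] != "positive").all()

    def test_seeded_determinism_byte_identical(self, tmp_path, small_config):
        dirs = []
        for name in ("a", "b"):
            out = tmp_path / name
            write_cohort(generate_cohort(small_config), out)
            dirs.append(out)
        for f in sorted(dirs[0].iterdir()):
            assert f.read_bytes() == (dirs[1] / f.name).read_bytes()

    def test_one_mention_label_per_note(self, small_cohort):
        assert small_cohort.truth["note_id"].is_unique
        assert small_cohort.truth["label"].isin(
            ["positive", "negated", "uncertain", "adult_onset", "indeterminate", "none"]
        ).all()

    def test_every_true_csa_patient_has_positive_note(self, small_cohort):
        by_pat = small_cohort.truth.groupby("patient_id")
        for pid, g in by_pat:
            if g["true_csa"].any():
                assert (g["label"] == "positive").any()
            else:
                assert not (g["label"] == "positive").any()

    def test_demographic_marginals_recovered(self):
        cfg = dataclasses.replace(CohortConfig(), n_patients=20000, seed=3)
        data = generate_cohort(cfg)
        share_f = (data.registry["sex"] == "F").mean()
        target = cfg.demographic_marginals["sex"]["F"]
        assert share_f == pytest.approx(target, abs=0.015)

    def test_exposed_demographics_shifted(self):
        cfg = dataclasses.replace(CohortConfig(), n_patients=20000, seed=3)
        data = generate_cohort(cfg)
        truth = data.truth.drop_duplicates("patient_id").set_index("patient_id")["true_csa"]
        reg = data.registry.set_index("patient_id")
        share_f_exposed = (reg.loc[truth[truth].index, "sex"] == "F").mean()
        share_f_unexposed = (reg.loc[truth[~truth].index, "sex"] == "F").mean()
        assert share_f_exposed > share_f_unexposed + 0.1

    def test_roundtrip_io(self, tmp_path, small_cohort):
        write_cohort(small_cohort, tmp_path)
        back = read_cohort(tmp_path)
        assert len(back.notes) == len(small_cohort.notes)
        assert back.truth["true_csa"].sum() == small_cohort.truth["true_csa"].sum()

    def test_dose_error_rate_recovered(self, gazetteer):
        """The share of >200%-of-max dose records matches the configured
        data-entry error rate within binomial noise."""
        from trauma_ehr.meddose import extract_medication_mentions

        cfg = dataclasses.replace(CohortConfig(), n_patients=1500, seed=13)
        cfg.med_params.dose_error_rate = 0.05
        data = generate_cohort(cfg)
        records = []
        for row in data.notes.itertuples(index=False):
            records.extend(
                extract_medication_mentions(row.note_id, row.patient_id, row.text, gazetteer)
            )
        dosed = [r for r in records if r.pct_max is not None]
        frac = np.mean([r.excluded for r in dosed])
        sd = np.sqrt(0.05 * 0.95 / len(dosed))
        assert len(dosed) > 500
        assert abs(frac - 0.05) <= 4 * sd


class TestConditionalProbs:
    def test_mixture_preserves_marginal(self):
        marginal = {"a": 0.6, "b": 0.3, "c": 0.1}
        shifts = {"a": 0.4, "b": -0.5}
        p_un, p_exp = conditional_category_probs(marginal, shifts, 0.1)
        for cat in marginal:
            mixed = 0.9 * p_un[cat] + 0.1 * p_exp[cat]
            assert mixed == pytest.approx(marginal[cat], abs=1e-12)

    def test_extreme_shift_rejected(self):
        with pytest.raises(ConfigError):
            conditional_category_probs({"a": 0.01, "b": 0.99}, {"a": 8.0}, 0.5)


class TestOutcomeSampling:
    def test_rates_follow_logistic_model(self):
        rng = np.random.default_rng(0)
        csa = np.repeat([False, True], 50000)
        eff = {"adm": OutcomeEffect(0.5, 0.65)}
        out = sample_binary_outcomes(csa, eff, rng)
        p0 = out.loc[~pd.Series(csa), "adm"].mean()
        p1 = out.loc[pd.Series(csa), "adm"].mean()
        assert p0 == pytest.approx(0.5, abs=0.01)
        assert p1 == pytest.approx(1 / (1 + np.exp(-0.65)), abs=0.01)


class TestNoteText:
    @pytest.mark.parametrize("label", ["positive", "negated", "uncertain",
                                       "adult_onset", "indeterminate", "none"])
    def test_label_drives_detector_outcome(self, detector, label):
        """Generated text must behave under the detector exactly as its
        ground-truth label promises."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            text = generate_note_text(label, rng)
            spans = detector.scan("n", text)
            flagged = flag_note(spans, detector.cutoff)
            if label == "positive":
                assert flagged
            else:
                assert not flagged
            if label == "indeterminate":
                assert any(s.polarity == "indeterminate" for s in spans)
            if label == "negated":
                assert any(s.polarity == "exclude" for s in spans)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            generate_note_text("bogus", np.random.default_rng(0))
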