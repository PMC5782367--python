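import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from legflux.config import Config
from legflux.datamodel import (
    average_occasion,
    load_cohort,
    mpe_to_ttr,
    steady_state_qc,
    ttr_to_mpe,
    validate_cohort,
)
from legflux.errors import (
    IncompleteOccasionError,
    IntegrityError,
    SchemaError,
    ValidationError,
)
from legflux.synthetic import generate_cohort
from legflux.config import SimulationConfig

from conftest import occasion_samples


@pytest.fixture
def cohort_dir(tmp_path):
    cfg = SimulationConfig(n_patients=4, seed=11)
    generate_cohort(cfg, tmp_path)
    return tmp_path


class TestLoadCohort:
    def test_minimal_valid_occasion_loads(self, tmp_path):
        samples = occasion_samples()
        pd.DataFrame([{"patient_id": "P001", "sex": "F", "age": 60.0,
                       "bmi": 25.0, "admission_weight": 80.0,
                       "diagnosis_class": "surgical"}]
                     ).to_csv(tmp_path / "patients.csv", index=False)
        pd.DataFrame([{"patient_id": "P001", "icu_day": 10,
                       "hematocrit": 0.3}]
                     ).to_csv(tmp_path / "occasions.csv", index=False)
        samples.to_csv(tmp_path / "samples.csv", index=False)
        pd.DataFrame([{"patient_id": "P001", "icu_day": 10,
                       "phe_ttr_muscle": 0.04}]
                     ).to_csv(tmp_path / "biopsies.csv", index=False)
        pd.DataFrame([{"patient_id": "P001", "icu_day": 10, "phase": ph,
                       "reading_index": i + 1, "slope_pct_per_min": 2.0}
                      for ph in ("pre", "post") for i in range(10)]
                     ).to_csv(tmp_path / "plethysmography.csv", index=False)
        cohort = load_cohort(tmp_path)
        assert len(cohort.occasions) == 1
        assert len(cohort.samples) == 8

    def test_round_trip_is_identity(self, cohort_dir, tmp_path):
        cohort = load_cohort(cohort_dir)
        out = tmp_path / "rt"
        cohort.write(out)
        reloaded = load_cohort(out)
        for attr in ("patients", "occasions", "samples", "biopsies", "pleth"):
            pd.testing.assert_frame_equal(getattr(cohort, attr),
                                          getattr(reloaded, attr))

    def test_bad_minute_rejected_naming_allowed_set(self, cohort_dir):
        cohort = load_cohort(cohort_dir)
        cohort.samples.loc[0, "minute"] = 130
        with pytest.raises(ValidationError, match=r"135.*140.*145.*150"):
            validate_cohort(cohort)

    def test_missing_column_names_it(self, cohort_dir):
        cohort = load_cohort(cohort_dir)
        cohort.occasions = cohort.occasions.drop(columns=["hematocrit"])
        with pytest.raises(SchemaError, match="hematocrit"):
            validate_cohort(cohort)

    def test_duplicate_sample_row_rejected(self, cohort_dir):
        cohort = load_cohort(cohort_dir)
        cohort.samples = pd.concat([cohort.samples, cohort.samples.iloc[:1]])
        with pytest.raises(IntegrityError):
            validate_cohort(cohort)

    @pytest.mark.parametrize("table,column,bad", [
        ("occasions", "hematocrit", 1.2),
        ("occasions", "hematocrit", 0.0),
        ("occasions", "icu_day", 0),
        ("patients", "age", -3.0),
        ("patients", "bmi", 0.0),
        ("samples", "phe_ttr", 1.5),
        ("samples", "phe", -1.0),
        ("biopsies", "phe_ttr_muscle", -0.01),
    ])
    def test_domain_violations_rejected(self, cohort_dir, table, column, bad):
        cohort = load_cohort(cohort_dir)
        frame = getattr(cohort, table)
        frame.loc[frame.index[0], column] = bad
        with pytest.raises((ValidationError, IntegrityError)):
            validate_cohort(cohort)

    # random-perturbation property: any field pushed outside its stated
    # domain must be rejected, whatever the row hit
    _PERTURBATIONS = {
        ("occasions", "hematocrit"): st.one_of(st.floats(-2, 0),
                                               st.floats(1, 3)),
        ("samples", "phe_ttr"): st.one_of(st.floats(-1, -1e-9),
                                          st.floats(1, 2)),
        ("samples", "phe"): st.floats(-100, -1e-6),
        ("patients", "age"): st.floats(-50, 0),
        ("biopsies", "phe_ttr_muscle"): st.floats(1, 2),
    }

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(data=st.data())
    def test_random_out_of_domain_perturbations_rejected(self, data):
        import dataclasses as dc
        from legflux.config import SimulationConfig
        from legflux.synthetic import simulate_cohort
        base, _ = simulate_cohort(SimulationConfig(n_patients=3), seed=6)
        cohort = dc.replace(
            base, **{a: getattr(base, a).copy()
                     for a in ("patients", "occasions", "samples",
                               "biopsies", "pleth")})
        (table, column), strat = data.draw(
            st.sampled_from(list(self._PERTURBATIONS.items())))
        bad = data.draw(strat)
        frame = getattr(cohort, table)
        row = data.draw(st.integers(0, len(frame) - 1))
        frame.loc[frame.index[row], column] = bad
        with pytest.raises(ValidationError):
            validate_cohort(cohort)


class TestAverageOccasion:
    def test_constant_series(self):
        av = average_occasion(occasion_samples(Ca=60.0), 0.04, 3.0)
        assert av.Ca == 60.0
        assert av.Em == 0.04
        assert av.PF == 3.0

    def test_arithmetic_mean_of_varying_series(self):
        samples = occasion_samples(jitter=[-2.0, 0.0, 2.0, 0.0])
        av = average_occasion(samples, 0.04, 3.0)
        assert av.Ca == pytest.approx(60.0, abs=1e-12)

    def test_permutation_invariance(self):
        samples = occasion_samples(jitter=[-2.0, 0.0, 2.0, 1.0])
        av1 = average_occasion(samples, 0.04, 3.0)
        av2 = average_occasion(samples.sample(frac=1, random_state=5),
                               0.04, 3.0)
        assert av1.Ca == av2.Ca
        assert av1.Ev == av2.Ev

    def test_incomplete_occasion_errors(self):
        samples = occasion_samples()
        partial = samples[samples["minute"] != 150]
        with pytest.raises(IncompleteOccasionError):
            average_occasion(partial, 0.04, 3.0)

    def test_partial_averaging_when_allowed(self):
        cfg = Config()
        cfg.qc.allow_partial = True
        samples = occasion_samples().iloc[:4]  # two timepoints per site
        with pytest.warns(UserWarning):
            av = average_occasion(samples, 0.04, 3.0, cfg)
        assert av.n_timepoints == 2

    def test_missing_biopsy_leaves_em_none(self):
        av = average_occasion(occasion_samples(), None, 3.0)
        assert av.Em is None


class TestSteadyStateQC:
    def test_constant_series_cv_zero(self):
        qc = steady_state_qc(occasion_samples())
        assert (qc["cv"] == 0).all()
        assert not qc["flag"].any()

    def test_known_cv_flagged(self):
        # arterial phe series {58,58,58,116} has CV = 0.4 > 0.15
        samples = occasion_samples(Ca=58.0, jitter=[0.0, 0.0, 0.0, 58.0])
        qc = steady_state_qc(samples)
        row = qc[(qc.site == "artery") & (qc.analyte == "phe")].iloc[0]
        assert row["cv"] == pytest.approx(0.4, rel=1e-12)
        assert row["flag"]

    def test_zero_mean_is_degenerate(self):
        samples = occasion_samples()
        samples["mh3"] = 0.0
        qc = steady_state_qc(samples)
        deg = qc[qc.analyte == "mh3"]
        assert deg["degenerate"].all()
        assert deg["flag"].all()


def test_enrichment_scale_conversions_are_inverses():
    ttr = np.array([0.0, 0.02, 0.08, 0.5])
    np.testing.assert_allclose(mpe_to_ttr(ttr_to_mpe(ttr)), ttr, atol=1e-15)
    assert ttr_to_mpe(0.08) == pytest.approx(0.08 / 1.08)
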