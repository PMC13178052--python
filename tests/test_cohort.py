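from datetime import date

import numpy as np
import pandas as pd
import pytest

from hfgap.cohort import (
    HF,
    NON_HF,
    CohortSpec,
    PreprocessorState,
    apply_preprocessor,
    apply_washout,
    assemble_cohorts,
    assert_no_leakage,
    assign_pseudo_index,
    build_features,
    completeness_filter,
    fit_preprocessor,
    icd_chapter,
    plausibility_filter,
)


def test_completeness_filter_requires_all_five_fields():
    demo = pd.DataFrame({
        "patient_id": list("abcde"),
        "age": [50, 60, 70, 40, 55],
        "sex": ["male"] * 5,
        "race": ["parda", "branca", None, "preta", "parda"],
        "height": [1.7] * 5,
        "weight": [70.0] * 5,
    })
    assert set(completeness_filter(demo)) == {"a", "b", "d", "e"}
    assert len(completeness_filter(demo.dropna())) == 4


def test_completeness_filter_empty_result_is_allowed():
    demo = pd.DataFrame({
        "patient_id": ["a"], "age": [None], "sex": ["male"],
        "race": ["parda"], "height": [1.7], "weight": [70.0]})
    assert len(completeness_filter(demo)) == 0


class TestWashout:
    first_i50 = {"case": date(2022, 6, 1)}

    def _events(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "event_date", "icd10", "procedure"])

    def test_event_366_days_before_index_is_kept(self):
        ev = self._events([("case", date(2021, 5, 31), "I25", None)])
        assert len(apply_washout(ev, self.first_i50)) == 1

    def test_boundary_day_is_inclusive(self):
        ev = self._events([("case", date(2021, 6, 1), "I25", None)])
        assert len(apply_washout(ev, self.first_i50)) == 1  # exactly 365 days

    def test_event_inside_washout_is_dropped(self):
        ev = self._events([("case", date(2021, 9, 1), "I25", None)])
        assert len(apply_washout(ev, self.first_i50)) == 0

    def test_control_2022_event_is_dropped(self):
        ev = self._events([("ctrl", date(2022, 1, 5), "I25", None)])
        assert len(apply_washout(ev, self.first_i50)) == 0

    def test_control_keeps_full_feature_window(self):
        ev = self._events([("ctrl", date(2018, 1, 1), "I25", None),
                           ("ctrl", date(2021, 12, 31), "I25", None)])
        assert len(apply_washout(ev, self.first_i50)) == 2

    def test_leakage_assertion_fires_on_contaminated_table(self):
        ev = self._events([("case", date(2021, 9, 1), "I25", None)])
        with pytest.raises(AssertionError):
            assert_no_leakage(ev, self.first_i50)
        ok = self._events([("case", date(2021, 5, 1), "I25", None)])
        assert_no_leakage(ok, self.first_i50)


def test_build_features_counts_codes_and_chapters():
    ev = pd.DataFrame({
        "patient_id": ["a"] * 4,
        "event_date": [date(2019, 1, 1)] * 4,
        "icd10": ["I25", "I251", "I259", "E78"],
        "procedure": [None, None, None, None],
    })
    demo = pd.DataFrame({"patient_id": ["a", "b"], "age": [60, 50],
                         "sex": ["male", "female"], "race": ["parda", "branca"],
                         "bmi": [25.0, 30.0]})
    out = build_features(ev, demo, case_ids={"a"}).set_index("patient_id")
    assert out.loc["a", "icd_I25"] == 3
    assert out.loc["a", "icd_E78"] == 1
    assert out.loc["a", "ch_IX"] == 3
    assert out.loc["a", "ch_IV"] == 1
    assert out.loc["a", "label"] == HF
    # patient with zero surviving events keeps an all-zero row
    assert out.loc["b", "icd_I25"] == 0
    assert out.loc["b", "label"] == NON_HF


def test_icd_chapter_mapping():
    assert icd_chapter("I500") == "IX"
    assert icd_chapter("E78") == "IV"
    assert icd_chapter("Z034") == "XXI"
    assert icd_chapter("B571") == "I"


def _feature_frame():
    rng = np.random.default_rng(0)
    n = 200
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "age": rng.normal(60, 10, n),
        "sex": rng.choice(["male", "female"], n),
        "race": rng.choice(["parda", "branca"], n),
        "bmi": rng.normal(27, 4, n),
        "icd_I25": rng.poisson(2, n),
        "proc_ECHO": rng.poisson(1, n),
    })


class TestPlausibility:
    def test_age_and_bmi_violations_drop_the_patient(self):
        f = _feature_frame()
        f.loc[0, "age"] = 17
        f.loc[1, "bmi"] = 61
        f.loc[2, "age"] = 111
        out = plausibility_filter(f)
        assert set(f["patient_id"][:3]).isdisjoint(out["patient_id"])
        expected_ok = (f["age"].between(18, 110) & f["bmi"].between(12, 60)).sum()
        assert len(out) == expected_ok

    def test_count_above_p99_cap_goes_missing_then_imputed(self):
        train = _feature_frame()
        state = fit_preprocessor(train)
        f = _feature_frame()
        f.loc[0, "icd_I25"] = 10_000
        capped = plausibility_filter(f, state)
        assert np.isnan(capped.loc[0, "icd_I25"])
        imputed = apply_preprocessor(state, capped)
        assert imputed["icd_I25"].notna().all()


class TestPreprocessor:
    def test_median_imputation_from_training_stats(self):
        train = _feature_frame()
        state = fit_preprocessor(train)
        apply_df = _feature_frame().head(5)
        apply_df.loc[0, "bmi"] = np.nan
        out = apply_preprocessor(state, apply_df).set_index("patient_id")
        assert out.loc["p0", "bmi"] == pytest.approx(train["bmi"].median())

    def test_fold_state_never_uses_apply_partition_statistics(self):
        fold_a, fold_b = _feature_frame(), _feature_frame()
        fold_b["bmi"] = fold_b["bmi"] + 100  # shift fold B wildly
        state = fit_preprocessor(fold_a)
        fold_b.loc[0, "bmi"] = np.nan
        out = apply_preprocessor(state, fold_b).set_index("patient_id")
        assert out.loc["p0", "bmi"] == pytest.approx(fold_a["bmi"].median())

    def test_one_hot_indicators_sum_to_one(self):
        state = fit_preprocessor(_feature_frame())
        out = apply_preprocessor(state, _feature_frame())
        sex_cols = [c for c in out.columns if c.startswith("sex__")]
        assert len(sex_cols) == 2
        assert (out[sex_cols].sum(axis=1) == 1).all()

    def test_state_round_trips_through_json(self, tmp_path):
        state = fit_preprocessor(_feature_frame(), standardize=True)
        path = tmp_path / "state.json"
        state.to_json(path)
        reloaded = PreprocessorState.from_json(path)
        f = _feature_frame()
        pd.testing.assert_frame_equal(
            apply_preprocessor(state, f), apply_preprocessor(reloaded, f))

    def test_entirely_missing_training_feature_is_an_error(self):
        f = _feature_frame()
        f["bmi"] = np.nan
        with pytest.raises(ValueError, match="bmi"):
            fit_preprocessor(f)


@pytest.fixture(scope="module")
def pool():
    n_cases, n_controls = 30_000, 30_000
    return pd.DataFrame({
        "patient_id": [f"c{i}" for i in range(n_cases)]
        + [f"n{i}" for i in range(n_controls)],
        "label": [HF] * n_cases + [NON_HF] * n_controls,
    })


@pytest.fixture(scope="module")
def cohorts(pool):
    return assemble_cohorts(pool, CohortSpec(seed=1)), pool


class TestAssembleCohorts:
    def test_development_cohort_size(self, cohorts):
        sets, _ = cohorts
        assert len(sets["development"]) == 19_995

    def test_low_prevalence_composition(self, cohorts):
        sets, pool = cohorts
        lp = set(sets["low_prevalence"])
        labels = pool.set_index("patient_id").loc[sorted(lp), "label"]
        assert len(lp) == 8_716
        assert (labels == HF).sum() == 175
        assert lp <= set(sets["validation_2"])

    def test_development_and_validations_pairwise_disjoint(self, cohorts):
        sets, _ = cohorts
        names = ["development", "validation_1", "validation_2"]
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert set(sets[a]).isdisjoint(sets[b])

    def test_split_is_stratified(self, cohorts):
        sets, pool = cohorts
        labels = pool.set_index("patient_id")["label"]
        train = labels.loc[sorted(set(sets["development_train"]))]
        test = labels.loc[sorted(set(sets["development_test"]))]
        assert abs((train == HF).sum() - round(0.8 * 10_000)) <= 1
        assert abs((test == HF).sum() - round(0.2 * 10_000)) <= 1
        assert set(sets["development_train"]).isdisjoint(sets["development_test"])

    def test_insufficient_stratum_names_itself(self, pool):
        spec = CohortSpec(n_cases=40_000, seed=1)
        with pytest.raises(ValueError, match="cases/development"):
            assemble_cohorts(pool, spec)

    def test_same_seed_reproduces_membership(self, pool):
        a = assemble_cohorts(pool, CohortSpec(seed=5))
        b = assemble_cohorts(pool, CohortSpec(seed=5))
        for k in a:
            assert np.array_equal(np.sort(a[k]), np.sort(b[k]))


def test_pseudo_index_mirrors_case_distribution():
    cases = [date(2022, m, 15) for m in range(1, 13)]
    mapping = assign_pseudo_index(["x", "y", "z"], cases, seed=0)
    assert set(mapping) == {"x", "y", "z"}
    assert all(pd.Timestamp(v).year == 2022 for v in mapping.values())
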