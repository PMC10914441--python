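"""Preprocessing contracts: L/R summation, TIV normalization, z-scores,
KS normality, training-set rule, outlier flags, table round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brainstages as bs
from brainstages.cohort_table import DataValidationError

from oracles import ks_statistic_by_hand


def _table(**cols):
    n = len(next(iter(cols.values())))
    base = dict(
        subject_id=[f"s{i}" for i in range(n)],
        cohort_id="c",
        group=["control"] * n,
        sex="F",
        age=np.linspace(20, 80, n),
        tiv_mm3=np.full(n, 1.5e6),
    )
    base.update(cols)
    return pd.DataFrame(base)


# ----------------------------------------------------------------- combine_lr

def test_symmetric_structures_sum_and_midline_passes_through():
    df = _table(thalamus_L=[7000.0, 7100.0], thalamus_R=[7200.0, 7300.0],
                brainstem=[22000.0, 23000.0])
    out = bs.combine_lr(df)
    assert out["thalamus"].tolist() == [14200.0, 14400.0]
    assert out["brainstem"].tolist() == [22000.0, 23000.0]
    assert "thalamus_L" not in out.columns


def test_missing_hemisphere_is_an_error_naming_the_structure():
    df = _table(thalamus_L=[7000.0, 7100.0])
    with pytest.raises(DataValidationError, match="thalamus"):
        bs.combine_lr(df)


# ----------------------------------------------------------- TIV normalization

def test_normalize_is_percent_of_tiv():
    assert bs.normalize_to_tiv(15000.0, 1.5e6) == pytest.approx(1.0)
    assert bs.normalize_to_tiv(0.0, 1.5e6) == 0.0
    with pytest.raises(DataValidationError):
        bs.normalize_to_tiv(10.0, 0.0)


@given(raw=st.floats(1.0, 1e6), tiv=st.floats(1e5, 3e6), k=st.floats(0.01, 100.0))
@settings(max_examples=50, deadline=None)
def test_normalization_invariant_to_common_unit_rescaling(raw, tiv, k):
    a = bs.normalize_to_tiv(raw, tiv)
    b = bs.normalize_to_tiv(raw * k, tiv * k)
    assert a == pytest.approx(b, rel=1e-12)


# --------------------------------------------------------------------- zscore

def test_zscore_standardizes_reference_to_mean_zero_sd_one(rng):
    ref = rng.normal(3.0, 0.5, 500)
    z = bs.zscore(ref, ref)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)
    assert bs.zscore(np.array([ref.mean()]), ref)[0] == pytest.approx(0.0, abs=1e-9)
    v = ref.mean() + 2 * ref.std(ddof=1)
    assert bs.zscore(np.array([v]), ref)[0] == pytest.approx(2.0, rel=1e-9)


def test_zscore_rejects_degenerate_reference():
    with pytest.raises(DataValidationError):
        bs.zscore([1.0], [2.0, 2.0])
    with pytest.raises(DataValidationError):
        bs.zscore([1.0], [2.0])


# -------------------------------------------------------------- KS normality

def test_ks_matches_hand_built_empirical_cdf_statistic(rng):
    x = rng.normal(2.0, 3.0, 400)
    res = bs.ks_normality(x)
    z = (x - x.mean()) / x.std(ddof=1)
    d_ref, p_ref = ks_statistic_by_hand(z)
    assert res.statistic == pytest.approx(d_ref, rel=1e-10)
    assert res.pvalue == pytest.approx(p_ref, rel=0.05)  # exact vs asymptotic null


def test_ks_accepts_normal_and_rejects_exponential_samples(rng):
    assert not bs.ks_normality(rng.normal(size=5000)).reject
    res = bs.ks_normality(rng.exponential(size=5000))
    assert res.tested and res.reject


def test_ks_flags_small_or_constant_samples_untested():
    assert not bs.ks_normality(np.ones(100)).tested
    assert not bs.ks_normality(np.arange(5.0)).tested


# ------------------------------------------------- disease training-set rule

def _records(control_ages, case_ages):
    ages = list(control_ages) + list(case_ages)
    groups = ["control"] * len(control_ages) + ["case"] * len(case_ages)
    return _table(age=np.array(ages, float), group=groups,
                  thalamus=np.full(len(ages), 14000.0))


def test_only_controls_strictly_younger_than_youngest_case_are_kept():
    out = bs.build_disease_training_set(_records([50.0, 60.0], [55.0, 70.0]))
    assert len(out) == 3
    kept_controls = out[out["group"] == "control"]["age"].tolist()
    assert kept_controls == [50.0]


def test_all_controls_older_than_cases_leaves_cases_only():
    out = bs.build_disease_training_set(_records([80.0, 90.0], [55.0]))
    assert (out["group"] == "case").all() and len(out) == 1


def test_empty_case_set_is_an_error():
    with pytest.raises(DataValidationError):
        bs.build_disease_training_set(_records([50.0], []))


@given(st.data())
@settings(max_examples=30, deadline=None)
def test_no_retained_control_reaches_the_youngest_case_age(data):
    ctrl = data.draw(st.lists(st.floats(1.0, 100.0), min_size=1, max_size=30))
    cases = data.draw(st.lists(st.floats(40.0, 90.0), min_size=1, max_size=10))
    out = bs.build_disease_training_set(_records(ctrl, cases))
    youngest = min(cases)
    assert (out.loc[out["group"] == "control", "age"] < youngest).all()
    assert len(out) == len(cases) + sum(a < youngest for a in ctrl)


# ---------------------------------------------------------- outlier flagging

def test_residuals_beyond_two_sigma_are_flagged(rng):
    ages = np.linspace(1, 100, 400)
    values = 0.5 + 0.01 * ages + rng.normal(0, 0.5, ages.size)
    model = bs.fit_trajectory(ages, values, "s", "control")
    series = bs.StructureSeries("s", ages, values, np.array(["control"] * 400),
                                reference_mean=1.0, reference_sd=0.1)
    sd = model.residual_sd
    series.values = model.predict(ages)          # everyone on the curve
    assert not bs.flag_model_outliers(series, model).any()
    series.values = model.predict(ages) + np.where(np.arange(400) < 5, 2.5, 1.9) * sd
    flags = bs.flag_model_outliers(series, model)
    assert flags[:5].all() and not flags[5:].any()


# -------------------------------------------------------------------- tables

def test_subject_table_round_trips_to_full_precision(tmp_path, small_cohort):
    subjects, _, _ = small_cohort
    path = tmp_path / "subjects.csv"
    bs.write_subject_table(subjects, path)
    back = bs.read_subject_table(path)
    pd.testing.assert_frame_equal(back, subjects.reset_index(drop=True))


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda d: d.drop(columns=["age"]), "missing required columns"),
        (lambda d: d.assign(age=np.nan), "missing values"),
        (lambda d: d.assign(age=130.0), "age must be"),
        (lambda d: d.assign(tiv_mm3=-1.0), "tiv_mm3 must be positive"),
        (lambda d: d.assign(group="patient"), "invalid group"),
    ],
)
def test_table_contract_violations_are_named(mutate, message):
    df = mutate(_table(thalamus=[14000.0, 15000.0]))
    with pytest.raises(DataValidationError, match=message):
        bs.cohort_table.validate_subject_table(df)
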