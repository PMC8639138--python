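"""Crude rates, nested hospitalisation models, PH check, correlations."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from kpdi.survival import (
    NestedHospitalisationModel,
    build_design,
    check_ph,
    correlations,
    crude_rate,
)


def test_crude_rate_arithmetic_identity():
    # 30 events over exactly 1000 person-years
    times = np.full(100, 10 * 365.25)
    events = np.zeros(100, dtype=bool)
    events[:30] = True
    rate = crude_rate(times, events)
    assert rate.rate == pytest.approx(30.0)
    assert rate.person_years == pytest.approx(1000.0)
    # Poisson-exact limits for k=30 (standard tables): 20.24, 42.83
    assert rate.ci_low == pytest.approx(20.24, abs=0.01)
    assert rate.ci_high == pytest.approx(42.83, abs=0.01)


def test_crude_rate_zero_events_and_zero_time():
    rate = crude_rate(np.full(10, 365.25), np.zeros(10, dtype=bool))
    assert rate.rate == 0.0 and rate.ci_low == 0.0
    # k=0 exact upper bound is chi2(0.975, 2)/2 = 3.6889 per 10 PY -> 368.9/1000
    assert rate.ci_high == pytest.approx(368.89, abs=0.01)
    with pytest.raises(ValueError):
        crude_rate(np.zeros(5), np.zeros(5, dtype=bool))


def test_crude_rate_hand_computed_toy_table():
    # 10 patients: 4 followed 2 years, 6 followed 0.5 years -> 11 PY; 3 events
    times = np.array([2.0] * 4 + [0.5] * 6) * 365.25
    events = np.array([True, False, True, False, True, False, False, False, False, False])
    rate = crude_rate(times, events)
    assert rate.person_years == pytest.approx(11.0)
    assert rate.rate == pytest.approx(1000 * 3 / 11.0)


def test_two_group_exponential_recovers_analytic_rate_ratio():
    # no censoring: the exponential MLE of the rate ratio is (d2/T2)/(d1/T1)
    rng = np.random.default_rng(6)
    n = 800
    x = np.repeat([0.0, 1.0], n // 2)
    lam = 0.2 * np.exp(np.log(2.0) * x)
    t = rng.exponential(1 / lam)
    frame = pd.DataFrame(
        {"time_days": t * 365.25, "event": True, "non_art_count": x}
    )
    cph = CoxPHFitter()
    cph.fit(frame, "time_days", "event")
    hr = float(np.exp(cph.params_["non_art_count"]))
    d1, d2 = n // 2, n // 2
    mle = (d2 / t[x == 1].sum()) / (d1 / t[x == 0].sum())
    low, high = np.exp(cph.confidence_intervals_.loc["non_art_count"])
    assert low < mle < high
    assert hr == pytest.approx(2.0, rel=0.15)


def _cohort_frame(n=3000, seed=0, beta_count=0.08):
    rng = np.random.default_rng(seed)
    count = rng.integers(0, 10, n).astype(float)
    frame = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "hiv": rng.random(n) < 0.3,
            "non_art_count": count,
            "age_years": rng.integers(40, 80, n),
            "sex": np.where(rng.random(n) < 0.1, "female", "male"),
            "race": rng.choice(["white", "black", "hispanic", "other"], n),
            "frailty": rng.normal(40, 12, n),
            "kpdi_category": rng.choice(["no_kpdi", "q1", "q2", "q3", "q4", "q5"], n),
        }
    )
    lam = 0.08 * np.exp(beta_count * (count - count.mean()))
    t = rng.exponential(1 / lam)
    frame["event"] = t < 9.5
    frame["time_days"] = np.minimum(t, 9.5) * 365.25
    return frame


def test_nested_models_share_risk_set_and_loglik_is_nondecreasing():
    frame = _cohort_frame()
    res = NestedHospitalisationModel(frame).fit()
    for stratum in ("hiv_negative", "hiv_positive"):
        lls = res.log_likelihoods(stratum)
        ordered = [lls[l] for l in ("unadjusted", "demographics", "+frailty", "+kpdi_index")]
        assert all(b >= a - 1e-6 for a, b in zip(ordered, ordered[1:]))
        n_at_risk = {f._n_examples for (s, _), f in res.fitters.items() if s == stratum}
        assert len(n_at_risk) == 1  # identical risk set at every level


def test_unadjusted_recovers_planted_count_effect_without_confounding():
    frame = _cohort_frame(n=6000, seed=3, beta_count=0.08)
    res = NestedHospitalisationModel(frame).fit(levels=["unadjusted"])
    table = res.table.set_index("stratum")
    for stratum in ("hiv_negative", "hiv_positive"):
        row = table.loc[stratum]
        assert row["ci_low"] < np.exp(0.08) < row["ci_high"]


def test_constant_covariate_dropped_other_estimates_survive(caplog):
    frame = _cohort_frame(n=1500, seed=5)
    frame["race"] = "white"
    with caplog.at_level("WARNING"):
        res = NestedHospitalisationModel(frame).fit(levels=["demographics"])
    assert "dropping constant covariates" in caplog.text
    covs = set(res.table["covariate"])
    assert "non_art_count" in covs and not any(c.startswith("race_") for c in covs)


def test_hr_invariant_to_patient_order():
    frame = _cohort_frame(n=1200, seed=7)
    res1 = NestedHospitalisationModel(frame).fit(levels=["unadjusted"])
    res2 = NestedHospitalisationModel(
        frame.sample(frac=1, random_state=11)
    ).fit(levels=["unadjusted"])
    h1 = res1.table.set_index("stratum")["hr"]
    h2 = res2.table.set_index("stratum")["hr"]
    assert h1["hiv_negative"] == pytest.approx(h2["hiv_negative"], rel=1e-8)


def test_design_codings_and_references():
    frame = pd.DataFrame(
        {
            "time_days": [100.0, 200.0],
            "event": [True, False],
            "non_art_count": [3, 5],
            "age_years": [60, 50],
            "sex": ["female", "male"],
            "race": ["missing", "black"],
            "frailty": [45.0, 30.0],
            "kpdi_category": ["q2", "q5"],
        }
    )
    design = build_design(frame)
    assert design["age_per_10"].tolist() == [6.0, 5.0]
    assert design["frailty_per_5"].tolist() == [9.0, 6.0]
    assert design["female"].tolist() == [1.0, 0.0]
    assert design["race_other"].tolist() == [1.0, 0.0]  # missing merges into other
    assert "kpdi_q2" not in design  # quintile 2 is the reference level
    assert design["kpdi_q5"].tolist() == [0.0, 1.0]


def test_check_ph_empty_and_flagging():
    frame = _cohort_frame(n=800, seed=9)
    res = NestedHospitalisationModel(frame).fit(levels=["unadjusted"])
    fitter = res.fitters[("hiv_negative", "unadjusted")]
    out = check_ph(fitter)
    assert list(out.columns) == ["covariate", "test_stat", "p", "flagged"]
    assert set(out["covariate"]) == {"non_art_count"}

    class EmptyParams:
        params_ = []

    assert check_ph(EmptyParams()).empty


def test_correlations_identity_sign_and_hand_value():
    x = pd.Series([1.0, 2, 3, 4, 5])
    frame = pd.DataFrame({"a": x, "b": -x, "c": [2.0, 1, 4, 3, 5]})
    out = correlations(frame).set_index(["x", "y"])
    assert out.loc[("a", "b"), "r"] == pytest.approx(-1.0)
    # hand computation: Sxy=8, Sxx=10, Syy=10 -> r=0.8
    assert out.loc[("a", "c"), "r"] == pytest.approx(0.8)


def test_correlations_zero_variance_reported_not_raised():
    frame = pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]})
    out = correlations(frame)
    row = out.iloc[0]
    assert np.isnan(row["r"]) and row["note"] == "zero variance"
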