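"""KPDI index: prevalence filter, bagged weights, scoring, quintiles."""

import numpy as np
import pandas as pd
import pytest

from kpdi.index import (
    NO_KPDI,
    assign_quintiles,
    bagged_weights,
    exposure_matrix,
    filter_prevalent,
    optimal_death_split_deviation,
    score_patients,
)
from kpdi.network import build_network


def coocc_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "drug_a", "drug_b", "overlap_days"])


def test_prevalence_filter_boundary_and_hand_count():
    net = build_network([("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"), ("I", "J")])
    rows = []
    for pair, prevalence in [
        (("A", "B"), 3), (("C", "D"), 10), (("E", "F"), 11), (("G", "H"), 50), (("I", "J"), 9)
    ]:
        rows += [(f"p{pair[0]}{i}", *pair, 100) for i in range(prevalence)]
    pairs = filter_prevalent(coocc_frame(rows), net, min_prevalence=10)
    assert pairs == [("C", "D"), ("E", "F"), ("G", "H")]


def test_prevalence_filter_ignores_non_edges():
    net = build_network([("A", "B")])
    rows = [(f"p{i}", "X", "Y", 30) for i in range(20)]
    assert filter_prevalent(coocc_frame(rows), net, min_prevalence=10) == []


def test_score_full_exposure_identity():
    weights = pd.DataFrame(
        {"drug_a": ["A"], "drug_b": ["B"], "beta_mean": [0.40]}
    )
    scores = score_patients(weights, coocc_frame([("p", "A", "B", 365)]), 365)
    assert scores.iloc[0]["score"] == pytest.approx(0.40)
    assert scores.iloc[0]["category"] == ""


def test_score_hand_arithmetic_two_pairs():
    weights = pd.DataFrame(
        {"drug_a": ["A", "C"], "drug_b": ["B", "D"], "beta_mean": [0.40, -0.20]}
    )
    coocc = coocc_frame([("p", "A", "B", 182.5), ("p", "C", "D", 365)])
    scores = score_patients(weights, coocc, 365)
    assert scores.iloc[0]["score"] == pytest.approx(0.40 * 0.5 - 0.20 * 1.0)


def test_patients_without_weighted_pairs_are_no_kpdi():
    weights = pd.DataFrame({"drug_a": ["A"], "drug_b": ["B"], "beta_mean": [0.5]})
    coocc = coocc_frame([("p1", "A", "B", 100), ("p2", "X", "Y", 100)])
    scores = score_patients(weights, coocc, 365, ["p1", "p2", "p3"])
    table = scores.set_index("patient_id")
    assert table.loc["p2", "category"] == NO_KPDI and table.loc["p2", "score"] == 0
    assert table.loc["p3", "category"] == NO_KPDI
    assert table.loc["p1", "n_pairs"] == 1


def test_scores_scale_linearly_with_weights_and_duration():
    rng = np.random.default_rng(4)
    rows = [
        (f"p{i}", "A", "B", int(rng.integers(1, 366))) for i in range(30)
    ] + [(f"p{i}", "C", "D", int(rng.integers(1, 366))) for i in range(15)]
    weights = pd.DataFrame(
        {"drug_a": ["A", "C"], "drug_b": ["B", "D"], "beta_mean": [0.3, -0.1]}
    )
    scaled = weights.assign(beta_mean=weights["beta_mean"] * 2.5)
    base = score_patients(weights, coocc_frame(rows), 365)
    double = score_patients(scaled, coocc_frame(rows), 365)
    np.testing.assert_allclose(double["score"], base["score"] * 2.5)


def _quintile_inputs(scores, death_flags, reference_flags=None):
    ids = [f"p{i:04d}" for i in range(len(scores))]
    frame = pd.DataFrame(
        {
            "patient_id": ids,
            "score": scores,
            "n_pairs": [1] * len(scores),
            "category": "",
        }
    )
    deaths = pd.Series(death_flags, index=ids)
    reference = pd.Series(
        reference_flags if reference_flags is not None else [True] * len(scores),
        index=ids,
    )
    return frame, deaths, reference


def test_hundred_distinct_score_deaths_split_exactly():
    scores = np.arange(100) / 10.0
    frame, deaths, ref = _quintile_inputs(scores, [True] * 100)
    q = assign_quintiles(frame, deaths, ref)
    assert q.reference_death_split == [20, 20, 20, 20, 20]


def test_tied_scores_stay_together():
    # all deaths at one score value: ties are never split across quintiles
    scores = [1.0] * 50 + [2.0] * 10
    deaths = [True] * 50 + [False] * 10
    frame, death_s, ref = _quintile_inputs(scores, deaths)
    q = assign_quintiles(frame, death_s, ref)
    assert sum(q.reference_death_split) == 50
    assert max(q.reference_death_split) == 50  # the tie block lands in one quintile


def test_too_few_reference_deaths_raise():
    frame, deaths, ref = _quintile_inputs([0.1, 0.2, 0.3], [True, True, False])
    with pytest.raises(ValueError, match="deaths"):
        assign_quintiles(frame, deaths, ref)


def test_no_kpdi_patients_never_enter_cutpoint_derivation():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=300).round(2)
    n_pairs = rng.integers(0, 3, 300)
    scores[n_pairs == 0] = 0.0
    ids = [f"p{i}" for i in range(300)]
    frame = pd.DataFrame(
        {"patient_id": ids, "score": scores, "n_pairs": n_pairs, "category": ""}
    )
    deaths = pd.Series(rng.random(300) < 0.3, index=ids)
    ref = pd.Series(True, index=ids)
    q1 = assign_quintiles(frame, deaths, ref)
    flipped = pd.Series(
        np.where(np.asarray(n_pairs) == 0, ~deaths.to_numpy(), deaths.to_numpy()),
        index=deaths.index,
    )
    q2 = assign_quintiles(frame, flipped, ref)
    np.testing.assert_allclose(q1.cutpoints, q2.cutpoints)
    assert (q1.categories[np.asarray(n_pairs) == 0] == NO_KPDI).all()


def test_quintiles_invariant_to_patient_id_relabelling():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=200)
    deaths = rng.random(200) < 0.4
    frame, death_s, ref = _quintile_inputs(scores, deaths)
    q1 = assign_quintiles(frame, death_s, ref)
    relabel = {f"p{i:04d}": f"z{999 - i:04d}" for i in range(200)}
    frame2 = frame.assign(patient_id=frame["patient_id"].map(relabel))
    q2 = assign_quintiles(
        frame2, death_s.rename(index=relabel), ref.rename(index=relabel)
    )
    np.testing.assert_allclose(q1.cutpoints, q2.cutpoints)
    assert (
        q1.categories.to_numpy() == q2.categories.to_numpy()
    ).all()  # same row order, same labels


def test_optimal_split_oracle_on_tiny_example():
    # deaths at scores 1..5, one each: perfect split has deviation 0
    scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    deaths = np.array([1, 1, 1, 1, 1])
    assert optimal_death_split_deviation(scores, deaths) == pytest.approx(0.0)
    # all deaths tied at one score: best any split can do is 4/5 of the total
    scores = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
    deaths = np.array([1, 1, 1, 1, 1])
    assert optimal_death_split_deviation(scores, deaths) == pytest.approx(4.0)


def test_bagged_weights_deterministic_for_fixed_seed():
    rng = np.random.default_rng(8)
    n = 300
    exposure = (rng.random((n, 2)) < 0.4).astype(float)
    frailty = rng.normal(40, 10, n)
    lam = 0.05 * np.exp(0.8 * exposure[:, 0])
    t = rng.exponential(1 / lam)
    events = t < 8
    t = np.minimum(t, 8) * 365.25
    args = (t, events, frailty, exposure, [("A", "B"), ("C", "D")])
    w1 = bagged_weights(*args, n_bags=3, seed=42)
    w2 = bagged_weights(*args, n_bags=3, seed=42)
    pd.testing.assert_frame_equal(w1, w2)
    assert (w1["prevalence"] == (exposure > 0).sum(axis=0)).all()


def test_bagged_weights_zero_without_events():
    n = 50
    rng = np.random.default_rng(1)
    exposure = (rng.random((n, 1)) < 0.5).astype(float)
    w = bagged_weights(
        np.full(n, 1000.0), np.zeros(n, dtype=bool), rng.normal(size=n),
        exposure, [("A", "B")], n_bags=2, seed=0,
    )
    assert (w["beta_mean"] == 0).all() and (w["n_significant"] == 0).all()


def test_exposure_matrix_binary_and_duration_modes():
    coocc = coocc_frame([("p1", "A", "B", 100), ("p2", "A", "B", 365)])
    pairs = [("A", "B")]
    binary = exposure_matrix(coocc, pairs, ["p1", "p2", "p3"])
    np.testing.assert_allclose(binary[:, 0], [1.0, 1.0, 0.0])
    frac = exposure_matrix(coocc, pairs, ["p1", "p2", "p3"], window_length=365)
    np.testing.assert_allclose(frac[:, 0], [100 / 365, 1.0, 0.0])
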