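"""Exposure calendars: episode merging, chronic rule, clipping, co-occurrence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bitmap_episodes, bitmap_pair_overlaps, calendar_fixture_frame
from kpdi.exposure import (
    ObservationWindow,
    build_episodes,
    chronic_drug_set,
    clip_to_window,
    co_occurrence,
    filter_chronic,
    medication_counts,
    patient_kpdi_counts,
)
from kpdi.network import build_network

WINDOW = ObservationWindow()  # days 0..364 relative to its own start


def _fills(records):
    return pd.DataFrame(records, columns=["patient_id", "drug_id", "fill_day", "days_supply"])


def test_every_fixture_case_matches_hand_derived_episodes(calendar_cases):
    episodes = build_episodes(calendar_fixture_frame())
    for case in calendar_cases:
        got = [
            (r.drug_id, r.start_day, r.end_day)
            for r in episodes[episodes["patient_id"] == case.name].itertuples()
        ]
        assert sorted(got) == sorted(case.episodes), case.name


def test_every_fixture_case_matches_bitmap_oracle(calendar_cases):
    episodes = build_episodes(calendar_fixture_frame())
    for case in calendar_cases:
        per_drug: dict[str, list] = {}
        for drug, day, supply in case.fills:
            per_drug.setdefault(drug, []).append((day, supply))
        expected = sorted(
            (drug, s, e)
            for drug, fills in per_drug.items()
            for s, e in bitmap_episodes(fills)
        )
        got = sorted(
            (r.drug_id, r.start_day, r.end_day)
            for r in episodes[episodes["patient_id"] == case.name].itertuples()
        )
        assert got == expected, case.name


def test_chronic_sets_match_hand_derivation(calendar_cases):
    episodes = build_episodes(calendar_fixture_frame())
    chronic = chronic_drug_set(episodes, WINDOW)
    for case in calendar_cases:
        assert chronic.get(case.name, set()) == case.chronic, case.name


def test_cooccurrence_matches_hand_counts_and_bitmap_oracle(calendar_cases):
    episodes = build_episodes(calendar_fixture_frame())
    clipped = clip_to_window(episodes, WINDOW)
    coocc = co_occurrence(clipped)
    for case in calendar_cases:
        rows = coocc[coocc["patient_id"] == case.name]
        got = {
            frozenset({r.drug_a, r.drug_b}): r.overlap_days for r in rows.itertuples()
        }
        if case.pairs or len({d for d, *_ in case.fills}) > 1:
            assert got == case.pairs, case.name
        oracle = bitmap_pair_overlaps(case.episodes, (0, 364))
        assert got == oracle, case.name


def test_episode_construction_is_order_independent_and_idempotent():
    fills = _fills(
        [("p", "A", 95, 90), ("p", "A", 0, 90), ("p", "B", 10, 100), ("p", "A", 215, 90)]
    )
    shuffled = fills.sample(frac=1, random_state=7)
    a = build_episodes(fills)
    b = build_episodes(shuffled)
    pd.testing.assert_frame_equal(a, b)


def test_non_positive_days_supply_rejected_with_warning(caplog):
    fills = _fills([("p", "A", 0, 0), ("p", "A", 10, -5), ("p", "B", 0, 90)])
    with caplog.at_level("WARNING"):
        episodes = build_episodes(fills)
    assert len(episodes) == 1 and episodes.iloc[0]["drug_id"] == "B"
    assert "non-positive" in caplog.text


def test_clip_drops_episodes_fully_outside_window():
    # A covers [-200, -111], B covers [400, 489]: both fully outside 0..364
    episodes = build_episodes(_fills([("p", "A", -200, 90), ("p", "B", 400, 90)]))
    assert clip_to_window(episodes, WINDOW).empty
    # C straddles the end: clipped to [360, 364]
    episodes = build_episodes(_fills([("p", "C", 360, 90)]))
    clipped = clip_to_window(episodes, WINDOW)
    assert [(r.start_day, r.end_day) for r in clipped.itertuples()] == [(360, 364)]


def test_clip_empty_input_passthrough():
    empty = build_episodes(_fills([]))
    assert clip_to_window(empty, WINDOW).empty
    assert co_occurrence(empty).empty


def test_medication_counts_split_art_and_non_art(toy_vocab):
    chronic = {
        "p1": {"DB01", "DB02", "DB03", "DB04", "DB05", "DB06", "DB07"},  # 2 ART + 5
        "p2": {"DB01", "DB02"},  # all ART
    }
    counts = medication_counts(chronic, toy_vocab)
    row1 = counts.set_index("patient_id").loc["p1"]
    row2 = counts.set_index("patient_id").loc["p2"]
    assert (row1["total_count"], row1["non_art_count"]) == (7, 5)
    assert (row2["total_count"], row2["non_art_count"]) == (2, 0)


def test_unknown_drug_counts_toward_total_with_flag(toy_vocab, caplog):
    with caplog.at_level("WARNING"):
        counts = medication_counts({"p": {"DB03", "MYSTERY"}}, toy_vocab)
    row = counts.iloc[0]
    assert row["total_count"] == 2 and row["non_art_count"] == 1
    assert "missing from vocabulary" in caplog.text


def test_filter_chronic_keeps_only_qualifying_pairs():
    episodes = build_episodes(
        _fills([("p", "A", 0, 200), ("p", "B", 0, 30), ("q", "A", 0, 30)])
    )
    chronic = chronic_drug_set(episodes, WINDOW)
    kept = filter_chronic(episodes, chronic)
    assert set(zip(kept["patient_id"], kept["drug_id"])) == {("p", "A")}


def test_patient_kpdi_counts_only_counts_network_edges():
    episodes = build_episodes(
        _fills([("p", "A", 0, 200), ("p", "B", 0, 200), ("p", "C", 0, 200)])
    )
    coocc = co_occurrence(clip_to_window(episodes, WINDOW))
    net = build_network([("A", "B")])
    counts = patient_kpdi_counts(coocc, net)
    assert counts.to_dict() == {"p": 1}


@settings(max_examples=30, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(-50, 380), st.integers(1, 120)), min_size=1, max_size=8
    )
)
def test_single_drug_episodes_match_bitmap_oracle(fills):
    frame = _fills([("p", "A", day, supply) for day, supply in fills])
    got = [
        (r.start_day, r.end_day) for r in build_episodes(frame).itertuples()
    ]
    assert got == bitmap_episodes(fills)


def test_overlap_days_never_exceed_window_length():
    episodes = build_episodes(
        _fills([("p", "A", -100, 600), ("p", "B", -50, 600)])
    )
    coocc = co_occurrence(clip_to_window(episodes, WINDOW))
    assert (coocc["overlap_days"] <= WINDOW.length_days).all()
    assert coocc.iloc[0]["overlap_days"] == 365


def test_window_validation_and_day_index():
    with pytest.raises(ValueError):
        ObservationWindow(WINDOW.end, WINDOW.start)
    assert WINDOW.day_range() == (0, 364)
    assert WINDOW.length_days == 365
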