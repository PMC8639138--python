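"""Shared fixtures: toy vocabulary, calendar fixture cases, bitmap oracle."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import pytest

from kpdi.vocab import DrugEntry, DrugVocabulary


@pytest.fixture(scope="session")
def toy_vocab() -> DrugVocabulary:
    """Ten-entry vocabulary: 7 plain drugs (2 with synonyms), 2 ART, 1 excluded."""
    return DrugVocabulary(
        [
            DrugEntry("DB01", "Atazanavir", frozenset({"Reyataz"}), "PI", False),
            DrugEntry("DB02", "Efavirenz", frozenset(), "NNRTI", False),
            DrugEntry("DB03", "Metformin", frozenset({"Glucophage"}), "non_art", False),
            DrugEntry("DB04", "Lisinopril", frozenset(), "non_art", False),
            DrugEntry("DB05", "Atorvastatin", frozenset(), "non_art", False),
            DrugEntry("DB06", "Omeprazole", frozenset(), "non_art", False),
            DrugEntry("DB07", "Sertraline", frozenset(), "non_art", False),
            DrugEntry("DB08", "Gabapentin", frozenset(), "non_art", False),
            DrugEntry("DB09", "Amlodipine", frozenset(), "non_art", False),
            DrugEntry("DB10", "Fish Oil", frozenset(), "non_art", True),
        ]
    )


# ---------------------------------------------------------------------------
# calendar fixture: fill histories with hand-derived expected episodes
# (day indices are relative to the observation-window start; the default
# window spans days 0..364)


@dataclass
class CalendarCase:
    name: str
    fills: list[tuple[str, int, int]]  # (drug, fill_day, days_supply)
    episodes: list[tuple[str, int, int]]  # expected merged (drug, start, end)
    chronic: set[str] = field(default_factory=set)  # expected chronic drugs
    pairs: dict[frozenset, int] = field(default_factory=dict)  # expected in-window overlaps


CALENDAR_CASES: list[CalendarCase] = [
    CalendarCase("single_90d", [("A", 0, 90)], [("A", 0, 89)], {"A"}),
    CalendarCase("single_89d_short", [("A", 0, 89)], [("A", 0, 88)], set()),
    CalendarCase(
        "merge_10d_gap", [("A", 0, 90), ("A", 100, 90)], [("A", 0, 189)], {"A"}
    ),
    CalendarCase(
        "merge_gap_exactly_30", [("A", 0, 30), ("A", 60, 30)], [("A", 0, 89)], {"A"}
    ),
    CalendarCase(
        "split_gap_31", [("A", 0, 30), ("A", 61, 30)], [("A", 0, 29), ("A", 61, 90)], set()
    ),
    CalendarCase(
        "split_gap_60", [("A", 0, 30), ("A", 90, 30)], [("A", 0, 29), ("A", 90, 119)], set()
    ),
    CalendarCase(
        "overlapping_fills", [("A", 0, 90), ("A", 30, 90)], [("A", 0, 119)], {"A"}
    ),
    CalendarCase("duplicate_fill", [("A", 0, 90), ("A", 0, 90)], [("A", 0, 89)], {"A"}),
    CalendarCase("before_window", [("A", -200, 90)], [("A", -200, -111)], set()),
    CalendarCase("straddle_start_90d", [("A", -30, 90)], [("A", -30, 59)], {"A"}),
    CalendarCase("straddle_start_chronic", [("A", -30, 120)], [("A", -30, 89)], {"A"}),
    CalendarCase("straddle_end", [("A", 330, 90)], [("A", 330, 419)], {"A"}),
    CalendarCase("cover_whole_window", [("A", -30, 430)], [("A", -30, 399)], {"A"}),
    CalendarCase(
        "three_fill_chain",
        [("A", 0, 90), ("A", 95, 90), ("A", 215, 90)],
        [("A", 0, 304)],
        {"A"},
    ),
    CalendarCase(
        "chain_breaks_at_31",
        [("A", 0, 90), ("A", 121, 90)],
        [("A", 0, 89), ("A", 121, 210)],
        {"A", },
    ),
    CalendarCase(
        "merge_90d_supply_30d_gap",
        [("A", 0, 90), ("A", 120, 90)],
        [("A", 0, 209)],
        {"A"},
    ),
    CalendarCase(
        "overlap_50_days",
        [("A", 0, 100), ("B", 50, 100)],
        [("A", 0, 99), ("B", 50, 149)],
        {"A", "B"},
        {frozenset({"A", "B"}): 50},
    ),
    CalendarCase(
        "touching_disjoint",
        [("A", 0, 50), ("B", 50, 50)],
        [("A", 0, 49), ("B", 50, 99)],
        set(),
        {},
    ),
    CalendarCase(
        "triple_full_overlap",
        [("A", 0, 365), ("B", 0, 365), ("C", 0, 365)],
        [("A", 0, 364), ("B", 0, 364), ("C", 0, 364)],
        {"A", "B", "C"},
        {
            frozenset({"A", "B"}): 365,
            frozenset({"A", "C"}): 365,
            frozenset({"B", "C"}): 365,
        },
    ),
    CalendarCase(
        "disjoint_episode_overlap_sums",
        [("A", 0, 50), ("A", 100, 50), ("B", 25, 100)],
        [("A", 0, 49), ("A", 100, 149), ("B", 25, 124)],
        {"B"},
        {frozenset({"A", "B"}): 50},  # 25 days in [25,49] + 25 days in [100,124]
    ),
    CalendarCase(
        "window_clip_limits_overlap",
        [("A", -100, 200), ("B", 0, 200)],
        [("A", -100, 99), ("B", 0, 199)],
        {"A", "B"},
        {frozenset({"A", "B"}): 100},  # shared days clipped to [0, 99]
    ),
    CalendarCase(
        "chronic_boundary_trio",
        [("A", 0, 200), ("B", 0, 90), ("C", 0, 60)],
        [("A", 0, 199), ("B", 0, 89), ("C", 0, 59)],
        {"A", "B"},
        {
            frozenset({"A", "B"}): 90,
            frozenset({"A", "C"}): 60,
            frozenset({"B", "C"}): 60,
        },
    ),
]


def calendar_fixture_frame() -> pd.DataFrame:
    """All fixture cases as one fill table, one synthetic patient per case."""
    rows = []
    for case in CALENDAR_CASES:
        for drug, day, supply in case.fills:
            rows.append(
                {
                    "patient_id": case.name,
                    "drug_id": drug,
                    "fill_day": day,
                    "days_supply": supply,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def calendar_cases() -> list[CalendarCase]:
    return CALENDAR_CASES


# ---------------------------------------------------------------------------
# independent day-bitmap oracle for episode merging and co-occurrence


def bitmap_episodes(
    fills: list[tuple[int, int]], refill_gap: int = 30
) -> list[tuple[int, int]]:
    """Episodes for one (patient, drug) from explicit covered-day sets.

    Marks every covered day, splits coverage into maximal runs, then joins
    consecutive runs separated by at most ``refill_gap`` uncovered days.
    Set-based and entirely independent of the vectorised implementation.
    """
    days: set[int] = set()
    for start, supply in fills:
        days.update(range(start, start + supply))
    if not days:
        return []
    ordered = sorted(days)
    runs = [[ordered[0], ordered[0]]]
    for d in ordered[1:]:
        if d == runs[-1][1] + 1:
            runs[-1][1] = d
        else:
            runs.append([d, d])
    merged = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] - 1 <= refill_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def bitmap_pair_overlaps(
    episodes: list[tuple[str, int, int]], window: tuple[int, int]
) -> dict[frozenset, int]:
    """Pairwise shared covered days within the window, by explicit day sets."""
    w0, w1 = window
    window_days = set(range(w0, w1 + 1))
    per_drug: dict[str, set[int]] = {}
    for drug, start, end in episodes:
        per_drug.setdefault(drug, set()).update(
            set(range(start, end + 1)) & window_days
        )
    out: dict[frozenset, int] = {}
    drugs = sorted(per_drug)
    for i, a in enumerate(drugs):
        for b in drugs[i + 1 :]:
            shared = len(per_drug[a] & per_drug[b])
            if shared > 0:
                out[frozenset({a, b})] = shared
    return out
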