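"""Exposure calendars: from pharmacy fills to episodes, chronic drugs and co-occurrence.

Fills (patient, drug, fill date, days supplied) are converted to exposure
episodes — maximal runs of covered days per (patient, drug), where a refill
starting within a configurable grace window (default 30 days) after the
previous coverage ends continues the same episode, the bridged gap counting
as covered. Episodes feed three downstream constructs:

* the *chronic* drug set per patient (some single episode of at least 90
  days touching the observation window),
* per-patient medication counts (total and non-ART), and
* the drug co-occurrence matrix: unordered drug pairs taken on at least one
  common day, with total overlap durations.

All day arithmetic is on inclusive integer day indices relative to an epoch
(by default the observation-window start), which keeps interval logic free
of calendar ambiguity.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import DrugVocabulary

logger = logging.getLogger(__name__)

EPISODE_COLUMNS = ["patient_id", "drug_id", "start_day", "end_day"]


@dataclass(frozen=True)
class ObservationWindow:
    """Inclusive calendar window for exposure ascertainment.

    Defaults to the 2009 US fiscal year (Oct 1 2008 – Sep 30 2009), the
    exposure year preceding outcome follow-up.
    """

    start: dt.date = dt.date(2008, 10, 1)
    end: dt.date = dt.date(2009, 9, 30)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("window end precedes start")

    @property
    def length_days(self) -> int:
        return (self.end - self.start).days + 1

    def day_index(self, date: dt.date, epoch: dt.date | None = None) -> int:
        return (date - (epoch or self.start)).days

    def day_range(self, epoch: dt.date | None = None) -> tuple[int, int]:
        """(first, last) inclusive day indices relative to ``epoch``."""
        return self.day_index(self.start, epoch), self.day_index(self.end, epoch)


def fills_to_day_index(fills: pd.DataFrame, epoch: dt.date) -> pd.DataFrame:
    """Convert an ISO-dated fill table to integer day indices.

    Expects columns patient_id, drug_id, fill_date (ISO-8601), days_supply;
    returns the same with ``fill_day`` replacing ``fill_date``.
    """
    out = fills.copy()
    dates = pd.to_datetime(out["fill_date"]).dt.date
    out["fill_day"] = [(d - epoch).days for d in dates]
    return out.drop(columns=["fill_date"])


def read_fills(path: str | Path, epoch: dt.date) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "drug_id": str})
    frame["days_supply"] = frame["days_supply"].astype(int)
    return fills_to_day_index(frame, epoch)


def build_episodes(fills: pd.DataFrame, refill_gap: int = 30) -> pd.DataFrame:
    """Merge fills into exposure episodes per (patient, drug).

    Each fill covers ``[fill_day, fill_day + days_supply - 1]``. A
    subsequent fill whose start is at most ``refill_gap`` days after the
    running coverage end joins the episode (bridged days count as covered);
    otherwise a new episode begins. Rows with non-positive days_supply are
    rejected with a warning. The result is order-independent: input rows
    are sorted internally.
    """
    fills = fills.copy()
    bad = fills["days_supply"] <= 0
    if bad.any():
        logger.warning("rejecting %d fill records with non-positive days_supply", int(bad.sum()))
        fills = fills[~bad]
    if fills.empty:
        return pd.DataFrame(columns=EPISODE_COLUMNS)

    fills = fills.sort_values(
        ["patient_id", "drug_id", "fill_day", "days_supply"], kind="mergesort"
    ).reset_index(drop=True)
    start = fills["fill_day"].to_numpy(dtype=np.int64)
    end = start + fills["days_supply"].to_numpy(dtype=np.int64) - 1

    group = (
        fills["patient_id"].astype(str) + "\x00" + fills["drug_id"].astype(str)
    )
    codes, _ = pd.factorize(group, sort=False)
    # Within-group running max of coverage end, via an offset trick that keeps
    # np.maximum.accumulate from leaking across group boundaries.
    span = end.max() - start.min() + 2
    offset = codes.astype(np.int64) * span
    running_end = np.maximum.accumulate(end + offset) - offset
    prev_end = np.empty_like(running_end)
    prev_end[1:] = running_end[:-1]
    new_group = np.empty(len(codes), dtype=bool)
    new_group[0] = True
    new_group[1:] = codes[1:] != codes[:-1]
    # Merge rule: a fill starting within `refill_gap` days after the previous
    # coverage end (i.e. gap of uncovered days <= refill_gap) continues the episode.
    new_episode = new_group | (start > prev_end + refill_gap + 1)
    episode_id = np.cumsum(new_episode)

    frame = pd.DataFrame(
        {
            "patient_id": fills["patient_id"].astype(str),
            "drug_id": fills["drug_id"].astype(str),
            "episode_id": episode_id,
            "start_day": start,
            "end_day": end,
        }
    )
    episodes = (
        frame.groupby(["patient_id", "drug_id", "episode_id"], sort=False)
        .agg(start_day=("start_day", "min"), end_day=("end_day", "max"))
        .reset_index()
        .drop(columns=["episode_id"])
        .sort_values(EPISODE_COLUMNS, kind="mergesort")
        .reset_index(drop=True)
    )
    return episodes


def clip_to_window(
    episodes: pd.DataFrame,
    window: ObservationWindow,
    epoch: dt.date | None = None,
) -> pd.DataFrame:
    """Intersect episodes with the observation window; drop empty remains."""
    if episodes.empty:
        return episodes.copy()
    w0, w1 = window.day_range(epoch)
    out = episodes.copy()
    out["start_day"] = out["start_day"].clip(lower=w0)
    out["end_day"] = out["end_day"].clip(upper=w1)
    out = out[out["end_day"] >= out["start_day"]]
    return out.sort_values(EPISODE_COLUMNS, kind="mergesort").reset_index(drop=True)


def chronic_drug_set(
    episodes: pd.DataFrame,
    window: ObservationWindow,
    min_days: int = 90,
    epoch: dt.date | None = None,
) -> dict[str, set[str]]:
    """Per-patient set of chronically used drugs.

    A drug qualifies when some single (un-clipped) episode spans at least
    ``min_days`` consecutive days and intersects the window — the episode
    may start before the window or run past it; days summed across separate
    episodes do not qualify.
    """
    if episodes.empty:
        return {}
    w0, w1 = window.day_range(epoch)
    length = episodes["end_day"] - episodes["start_day"] + 1
    ok = (
        (length >= min_days)
        & (episodes["start_day"] <= w1)
        & (episodes["end_day"] >= w0)
    )
    qualifying = episodes[ok]
    return {
        patient: set(group["drug_id"])
        for patient, group in qualifying.groupby("patient_id", sort=True)
    }


def filter_chronic(episodes: pd.DataFrame, chronic: dict[str, set[str]]) -> pd.DataFrame:
    """Keep only episodes of (patient, drug) pairs in the chronic sets."""
    if episodes.empty:
        return episodes.copy()
    keys = set()
    for patient, drugs in chronic.items():
        keys.update((patient, d) for d in drugs)
    mask = [
        (p, d) in keys
        for p, d in zip(episodes["patient_id"], episodes["drug_id"])
    ]
    return episodes[np.asarray(mask, dtype=bool)].reset_index(drop=True)


def medication_counts(
    chronic_sets: dict[str, set[str]], vocab: DrugVocabulary
) -> pd.DataFrame:
    """Total and non-ART chronic medication counts per patient.

    Unknown drug ids count toward the total and are flagged with a warning;
    non-ART counts include only drugs the vocabulary marks ``non_art``.
    """
    non_art = vocab.non_art_ids
    known = vocab.drug_ids
    rows = []
    n_unknown = 0
    for patient in sorted(chronic_sets):
        drugs = chronic_sets[patient]
        unknown = drugs - known
        n_unknown += len(unknown)
        rows.append(
            {
                "patient_id": patient,
                "total_count": len(drugs),
                "non_art_count": len(drugs & non_art),
            }
        )
    if n_unknown:
        logger.warning("%d chronic drug ids missing from vocabulary", n_unknown)
    return pd.DataFrame(rows, columns=["patient_id", "total_count", "non_art_count"])


def co_occurrence(episodes: pd.DataFrame) -> pd.DataFrame:
    """Drug co-occurrence matrix from (already clipped) episodes.

    For each patient, every unordered pair of distinct drugs sharing at
    least one covered day appears exactly once, with ``overlap_days`` the
    total number of shared days summed across all episode intersections.
    Pass window-clipped episodes to restrict overlaps to the observation
    window.
    """
    cols = ["patient_id", "drug_a", "drug_b", "overlap_days"]
    if episodes.empty:
        return pd.DataFrame(columns=cols)
    left = episodes.rename(
        columns={"drug_id": "drug_a", "start_day": "start_a", "end_day": "end_a"}
    )
    right = episodes.rename(
        columns={"drug_id": "drug_b", "start_day": "start_b", "end_day": "end_b"}
    )
    merged = left.merge(right, on="patient_id")
    merged = merged[merged["drug_a"] < merged["drug_b"]]
    overlap = (
        np.minimum(merged["end_a"], merged["end_b"])
        - np.maximum(merged["start_a"], merged["start_b"])
        + 1
    )
    merged = merged.assign(overlap_days=overlap)
    merged = merged[merged["overlap_days"] > 0]
    out = (
        merged.groupby(["patient_id", "drug_a", "drug_b"], sort=True)["overlap_days"]
        .sum()
        .reset_index()
    )
    return out[cols]


def patient_kpdi_counts(coocc: pd.DataFrame, net) -> pd.Series:
    """Number of co-occurring pairs per patient that are interaction edges."""
    if coocc.empty:
        return pd.Series(dtype=int, name="kpdi_count")
    is_edge = [
        net.has_interaction(a, b) for a, b in zip(coocc["drug_a"], coocc["drug_b"])
    ]
    hits = coocc[np.asarray(is_edge, dtype=bool)]
    counts = hits.groupby("patient_id").size()
    counts.name = "kpdi_count"
    return counts
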