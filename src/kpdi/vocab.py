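"""Drug vocabulary: canonical names, synonyms, ART-class flags and exclusions.

The vocabulary stands in for a licensed interaction catalogue's drug list.
Each entry carries an opaque ``drug_id``, a canonical name, a set of
synonyms, an antiretroviral-therapy (ART) class, and an ``excluded`` flag
marking items that are dropped from analysis (supplements, vaccines, water,
non-specific topicals and similar non-drugs).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: Recognised ART classes. ``non_art`` marks every drug that counts toward
#: the non-ART medication count.
ART_CLASSES = frozenset(
    {"PI", "NNRTI", "NRTI", "INSTI", "booster", "other_art", "non_art"}
)

_WS = re.compile(r"\s+")


def normalise_name(name: str) -> str:
    """Case-fold and collapse internal whitespace for name matching."""
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class DrugEntry:
    drug_id: str
    canonical_name: str
    synonyms: frozenset[str] = field(default_factory=frozenset)
    art_class: str = "non_art"
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.art_class not in ART_CLASSES:
            raise ValueError(
                f"unknown art_class {self.art_class!r} for drug {self.drug_id!r}"
            )


class DrugVocabulary:
    """Lookup table of drugs keyed by id, with name-based resolution.

    Invariants enforced at construction: drug ids are unique, and every
    canonical name or synonym resolves (case-insensitively, whitespace
    normalised) to exactly one drug.
    """

    def __init__(self, entries: Iterable[DrugEntry]):
        self._entries: dict[str, DrugEntry] = {}
        self._name_index: dict[str, str] = {}
        for entry in entries:
            if entry.drug_id in self._entries:
                raise ValueError(f"duplicate drug_id {entry.drug_id!r}")
            self._entries[entry.drug_id] = entry
        for entry in self._entries.values():
            for name in (entry.canonical_name, *entry.synonyms):
                key = normalise_name(name)
                owner = self._name_index.get(key)
                if owner is not None and owner != entry.drug_id:
                    raise ValueError(
                        f"name {name!r} maps to both {owner!r} and {entry.drug_id!r}"
                    )
                self._name_index[key] = entry.drug_id

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._entries

    def __getitem__(self, drug_id: str) -> DrugEntry:
        return self._entries[drug_id]

    def __iter__(self):
        return iter(self._entries.values())

    # -- id sets ------------------------------------------------------------
    @property
    def drug_ids(self) -> set[str]:
        return set(self._entries)

    @property
    def non_excluded_ids(self) -> set[str]:
        return {e.drug_id for e in self if not e.excluded}

    @property
    def non_art_ids(self) -> set[str]:
        return {e.drug_id for e in self if e.art_class == "non_art" and not e.excluded}

    @property
    def art_ids(self) -> set[str]:
        return {e.drug_id for e in self if e.art_class != "non_art" and not e.excluded}

    def is_art(self, drug_id: str) -> bool:
        entry = self._entries.get(drug_id)
        return entry is not None and entry.art_class != "non_art"

    def resolve(self, name: str) -> str | None:
        """Return the drug_id a name maps to, or None."""
        return self._name_index.get(normalise_name(name))

    # -- (de)serialisation --------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DrugVocabulary":
        required = {"drug_id", "canonical_name", "synonyms", "art_class", "excluded"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"vocabulary table missing columns: {sorted(missing)}")
        entries = []
        for row in frame.itertuples(index=False):
            syn_raw = row.synonyms
            if syn_raw is None or (isinstance(syn_raw, float) and pd.isna(syn_raw)):
                syn_raw = ""
            synonyms = frozenset(s.strip() for s in str(syn_raw).split("|") if s.strip())
            excluded = str(row.excluded).strip().lower() in {"1", "true", "yes"}
            entries.append(
                DrugEntry(
                    drug_id=str(row.drug_id),
                    canonical_name=str(row.canonical_name),
                    synonyms=synonyms,
                    art_class=str(row.art_class),
                    excluded=excluded,
                )
            )
        return cls(entries)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DrugVocabulary":
        return cls.from_frame(
            pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug_id": e.drug_id,
                "canonical_name": e.canonical_name,
                "synonyms": "|".join(sorted(e.synonyms)),
                "art_class": e.art_class,
                "excluded": str(e.excluded).lower(),
            }
            for e in sorted(self, key=lambda e: e.drug_id)
        ]
        return pd.DataFrame(
            rows, columns=["drug_id", "canonical_name", "synonyms", "art_class", "excluded"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class NameMappingResult:
    """Outcome of resolving raw prescription names against a vocabulary.

    Every distinct raw name lands in exactly one of ``mapping`` (resolved
    to a non-excluded drug), ``excluded`` (resolved to a flagged non-drug)
    or ``unmapped``. Duplicate raw names are reported once, with their
    multiplicity in ``multiplicity``.
    """

    mapping: dict[str, str]
    unmapped: list[str]
    excluded: list[str]
    multiplicity: Counter

    def __post_init__(self) -> None:
        buckets = [set(self.mapping), set(self.unmapped), set(self.excluded)]
        total = sum(len(b) for b in buckets)
        if total != len(set().union(*buckets)):
            raise ValueError("mapping buckets overlap")


def map_drug_names(
    raw_names: Iterable[str], vocab: DrugVocabulary
) -> NameMappingResult:
    """Resolve raw drug names to vocabulary ids.

    Matching is exact after case-folding and whitespace normalisation,
    against canonical names and synonyms alike (the index is shared, so
    canonical matches and synonym matches are indistinguishable by
    construction). No fuzzy matching is attempted: residual names are
    returned in ``unmapped`` for manual curation.
    """
    multiplicity: Counter = Counter()
    first_spelling: dict[str, str] = {}
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    excluded: list[str] = []
    for raw in raw_names:
        key = normalise_name(raw)
        multiplicity[first_spelling.setdefault(key, raw)] += 1
        if multiplicity[first_spelling[key]] > 1:
            continue
        drug_id = vocab.resolve(raw)
        if drug_id is None:
            unmapped.append(raw)
        elif vocab[drug_id].excluded:
            excluded.append(raw)
        else:
            mapping[raw] = drug_id
    return NameMappingResult(mapping, unmapped, excluded, multiplicity)


def apply_combo_split(
    fills: pd.DataFrame, combo_map: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Expand co-formulated products into one fill row per component.

    ``combo_map`` maps a combination-product drug_id to its component
    drug_ids; each matching fill row is replaced by identical rows for the
    components, so each component is counted separately downstream.
    """
    if not combo_map:
        return fills
    is_combo = fills["drug_id"].isin(combo_map)
    plain = fills[~is_combo]
    pieces = [plain]
    for combo_id, components in combo_map.items():
        rows = fills[fills["drug_id"] == combo_id]
        for comp in components:
            piece = rows.copy()
            piece["drug_id"] = comp
            pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(list(out.columns)).reset_index(drop=True)
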