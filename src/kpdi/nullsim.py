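"""Random drug-set null for interaction counts, observed summaries, and linear fits.

The null model asks how many pairwise interactions a patient on *k*
medications would carry if the medications were chosen uniformly at random
from the drug universe: for each set size k (2..12 by default) many sets
are drawn without replacement and the interaction edges within each set
are counted. Observed per-patient interaction counts, stratified by group
and medication count, are summarised on the same scale, and ordinary
least-squares lines through the per-count means quantify the contrast —
real-world prescribing concentrates interacting drugs well above chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import patient_kpdi_counts
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_SIZES = range(2, 13)
#: Null-population size per set size; the source analysis drew one random
#: set per cohort member on >=2 medications.
DEFAULT_N_SETS = 44_350


@dataclass(frozen=True)
class KPDICountSummary:
    """Distribution summary of interaction counts at one set size."""

    set_size: int
    n_sets: int
    min: float
    max: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if not (self.min <= self.mean <= self.max):
            raise ValueError("summary violates min <= mean <= max")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared outside [0, 1]")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def _summary_from_counts(set_size: int, counts: np.ndarray) -> KPDICountSummary:
    return KPDICountSummary(
        set_size=set_size,
        n_sets=len(counts),
        min=float(counts.min()),
        max=float(counts.max()),
        mean=float(counts.mean()),
        sd=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
    )


def random_drug_sets(
    net: InteractionNetwork,
    set_size: int,
    n_sets: int,
    seed: int | np.random.Generator,
    universe: Sequence[str] | None = None,
) -> list[set[str]]:
    """Uniform without-replacement drug sets from the network's node universe.

    ``universe`` restricts sampling (e.g. to cohort-observed drugs);
    default is every network node. Reproducible for a given seed.
    """
    idx, order = _random_index_sets(net, set_size, n_sets, seed, universe)
    order = np.asarray(order, dtype=object)
    return [set(order[row]) for row in idx]


def _random_index_sets(
    net: InteractionNetwork,
    set_size: int,
    n_sets: int,
    seed: int | np.random.Generator,
    universe: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    universe = sorted(net.nodes) if universe is None else sorted(universe)
    if set_size > len(universe):
        raise ValueError(
            f"set_size {set_size} exceeds universe of {len(universe)} drugs"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Without-replacement draw per row: take the `set_size` smallest of a row
    # of uniforms (argpartition), a vectorised equivalent of rng.choice.
    keys = rng.random((n_sets, len(universe)))
    idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    return idx, universe


def count_kpdis_batch(sets_idx: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Interaction counts for many index sets against a dense adjacency."""
    sub = adjacency[sets_idx[:, :, None], sets_idx[:, None, :]]
    return sub.sum(axis=(1, 2)) // 2


def summarize_random_kpdis(
    net: InteractionNetwork,
    sizes: Iterable[int] = DEFAULT_SIZES,
    n_sets: int = DEFAULT_N_SETS,
    seed: int | np.random.Generator = 0,
    universe: Sequence[str] | None = None,
) -> list[KPDICountSummary]:
    """Null distribution of interaction counts per set size.

    On an Erdős–Rényi universe of density p the expected count at size k
    is p·k(k−1)/2; the near-linear appearance over k = 2..12 is the small-k
    face of that quadratic.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe_sorted = sorted(net.nodes) if universe is None else sorted(universe)
    adjacency, _ = net.adjacency(universe_sorted)
    summaries = []
    for size in sizes:
        idx, _ = _random_index_sets(net, size, n_sets, rng, universe_sorted)
        counts = count_kpdis_batch(idx, adjacency)
        summaries.append(_summary_from_counts(size, counts))
    return summaries


def summaries_to_frame(summaries: Iterable[KPDICountSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def observed_kpdis_by_count(
    coocc: pd.DataFrame,
    counts: pd.DataFrame,
    net: InteractionNetwork,
    group_labels: Mapping[str, str] | pd.Series | None = None,
    count_col: str = "total_count",
    sizes: Iterable[int] = DEFAULT_SIZES,
) -> pd.DataFrame:
    """Observed per-patient interaction counts summarised by group and count.

    ``counts`` is the per-patient medication-count table; patients present
    there but absent from the co-occurrence matrix carry zero interacting
    pairs. Strata outside ``sizes`` or left empty are omitted (with a
    warning for the latter). Returns tidy rows: group, set_size, n_sets,
    min, max, mean, sd.
    """
    sizes = list(sizes)
    kpdi = patient_kpdi_counts(coocc, net)
    table = counts.set_index("patient_id").copy()
    table["kpdi_count"] = kpdi.reindex(table.index).fillna(0).astype(int)
    if group_labels is None:
        table["group"] = "all"
    else:
        table["group"] = pd.Series(dict(group_labels) if isinstance(group_labels, Mapping) else group_labels).reindex(table.index)
    rows = []
    for group, gframe in table.groupby("group", sort=True):
        for size in sizes:
            counts_here = gframe.loc[gframe[count_col] == size, "kpdi_count"].to_numpy()
            if len(counts_here) == 0:
                logger.warning("empty stratum: group=%s medication count=%d", group, size)
                continue
            summary = _summary_from_counts(size, counts_here)
            rows.append({"group": group, **vars(summary)})
    return pd.DataFrame(rows)


def fit_linear(points: Iterable[tuple[float, float]]) -> LinearFit:
    """Ordinary least squares through (medication count, mean interaction count).

    Requires at least two distinct x values; a vertical stack of points has
    no defined slope and raises.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two points")
    x, y = pts[:, 0], pts[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("slope undefined: all x values identical")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def fit_mean_curve(summary_frame: pd.DataFrame) -> LinearFit:
    """Linear fit of mean interaction count against set size for one group."""
    return fit_linear(zip(summary_frame["set_size"], summary_frame["mean"]))
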