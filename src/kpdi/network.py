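"""Drug interaction network: drugs as nodes, known pairwise interactions as edges.

The network is the lookup structure behind every interaction count: a set of
drugs in which an undirected edge records a catalogued pairwise interaction
(KPDI). Membership queries are order-invariant and self-interactions are
not representable.
"""

from __future__ import annotations

import logging
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .vocab import DrugVocabulary

logger = logging.getLogger(__name__)


class InteractionNetwork:
    """Undirected drug-interaction graph with fast pair counting.

    Thin wrapper around :class:`networkx.Graph` that enforces no
    self-loops and exposes the operations the exposure and simulation
    code needs: pair membership, interaction counting within a drug set,
    and a dense adjacency view for batched counting.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._graph = graph if graph is not None else nx.Graph()
        loops = list(nx.selfloop_edges(self._graph))
        if loops:
            raise ValueError(f"self-loops are not valid interactions: {loops[:3]}")

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self._graph.edges}

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def has_interaction(self, a: str, b: str) -> bool:
        """True if drugs a and b have a catalogued interaction (order-free)."""
        if a == b:
            return False
        return self._graph.has_edge(a, b)

    def count_kpdis(self, drug_set: Iterable[str]) -> int:
        """Number of interacting unordered pairs within ``drug_set``.

        Unknown drugs contribute no edges; the result is bounded by
        C(len(set), 2).
        """
        drugs = set(drug_set)
        g = self._graph
        return sum(1 for a, b in combinations(drugs, 2) if g.has_edge(a, b))

    def adjacency(self, order: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Dense boolean adjacency matrix and the node order used.

        Intended for batched set counting in the null simulation; nodes
        absent from the network get all-zero rows.
        """
        if order is None:
            order = sorted(self._graph.nodes)
        order = list(order)
        idx = {d: i for i, d in enumerate(order)}
        mat = np.zeros((len(order), len(order)), dtype=bool)
        for a, b in self._graph.edges:
            ia, ib = idx.get(a), idx.get(b)
            if ia is not None and ib is not None:
                mat[ia, ib] = mat[ib, ia] = True
        return mat, order

    def to_edge_frame(self) -> pd.DataFrame:
        rows = sorted(tuple(sorted(e)) for e in self._graph.edges)
        return pd.DataFrame(rows, columns=["drug_id_a", "drug_id_b"])


def build_network(
    edge_rows: Iterable[tuple[str, str]],
    vocab: DrugVocabulary | None = None,
    on_unknown: str = "warn",
) -> InteractionNetwork:
    """Assemble an interaction network from two-column edge rows.

    Self-loops are dropped with a warning and duplicate edges (in either
    order) collapse. With a vocabulary, the node set is the union of edge
    endpoints and all non-excluded vocabulary drugs, and edges touching
    unknown drug ids are skipped with a warning (``on_unknown='warn'``) or
    raise (``'error'``).
    """
    if on_unknown not in {"warn", "error"}:
        raise ValueError("on_unknown must be 'warn' or 'error'")
    g = nx.Graph()
    known = vocab.drug_ids if vocab is not None else None
    n_loops = n_unknown = 0
    for a, b in edge_rows:
        a, b = str(a), str(b)
        if a == b:
            n_loops += 1
            continue
        if known is not None and (a not in known or b not in known):
            if on_unknown == "error":
                raise KeyError(f"edge ({a!r}, {b!r}) references unknown drug_id")
            n_unknown += 1
            continue
        g.add_edge(a, b)
    if n_loops:
        logger.warning("dropped %d self-loop edge rows", n_loops)
    if n_unknown:
        logger.warning("skipped %d edge rows with unknown drug ids", n_unknown)
    if vocab is not None:
        g.add_nodes_from(vocab.non_excluded_ids)
    return InteractionNetwork(g)


def count_kpdis(drug_set: Iterable[str], net: InteractionNetwork) -> int:
    """Functional alias for :meth:`InteractionNetwork.count_kpdis`."""
    return net.count_kpdis(drug_set)


def read_edge_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column interaction edge list (TSV/CSV, '#' comments)."""
    frame = pd.read_csv(
        path, sep=None, engine="python", dtype=str, comment="#", keep_default_na=False
    )
    required = {"drug_id_a", "drug_id_b"}
    if not required <= set(frame.columns):
        raise ValueError(
            f"edge table needs columns {sorted(required)}, got {list(frame.columns)}"
        )
    return list(zip(frame["drug_id_a"], frame["drug_id_b"]))


def write_edge_table(net: InteractionNetwork, path: str | Path) -> None:
    net.to_edge_frame().to_csv(path, sep="\t", index=False)
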