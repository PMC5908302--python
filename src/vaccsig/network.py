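"""Interaction-list merging and connector-gene identification.

Each signature (seed) gene comes with per-source nearest-neighbor lists
(e.g. one list from each of two interaction databases).  Sources are merged
per seed by set union after upper-casing symbols; a *connector* is a
non-seed neighbor appearing in the merged lists of two or more seeds, its
degree being the number of distinct seeds whose lists contain it.  A seed
appearing in another seed's list yields a direct seed-seed edge and is never
reported as a connector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = ["InteractionLists", "ConnectorNetwork", "read_interaction_tsv",
           "merge_sources", "find_connectors"]


@dataclass
class InteractionLists:
    """Per-seed, per-source neighbor sets.

    ``neighbors[seed][source]`` is the set of neighbor symbols reported for
    that seed by that source.
    """

    neighbors: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, seed: str, source: str, partners: Iterable[str]) -> None:
        seed = seed.strip().upper()
        bucket = self.neighbors.setdefault(seed, {}).setdefault(source, set())
        bucket.update(p.strip().upper() for p in partners)

    @property
    def seed_genes(self) -> list[str]:
        return sorted(self.neighbors)


def read_interaction_tsv(path: str | Path, source: str,
                         lists: InteractionLists | None = None
                         ) -> InteractionLists:
    """Read a two-column (seed, neighbor) TSV into an InteractionLists,
    optionally extending an existing one with a further source."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"seed", "neighbor"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'seed' and 'neighbor'")
    lists = lists if lists is not None else InteractionLists()
    for r in df.itertuples():
        lists.add(r.seed, source, [r.neighbor])
    return lists


def merge_sources(lists: InteractionLists) -> dict[str, set[str]]:
    """Set-union of all sources per seed (symbols case-normalized)."""
    if not lists.neighbors:
        raise ValueError("no seed genes")
    return {seed: set().union(*sources.values()) if sources else set()
            for seed, sources in lists.neighbors.items()}


@dataclass
class ConnectorNetwork:
    """Merged seed-neighbor network with connector annotations."""

    graph: nx.Graph
    connector_degree: dict[str, int]
    edges: list[tuple[str, str]]

    def connectors(self) -> list[str]:
        """Connector symbols, highest degree first, then alphabetical."""
        return sorted(self.connector_degree,
                      key=lambda g: (-self.connector_degree[g], g))


def find_connectors(merged: Mapping[str, Iterable[str]],
                    min_degree: int = 2) -> ConnectorNetwork:
    """Identify connectors: neighbors present in >= ``min_degree`` distinct
    seeds' merged lists.  Returns the full seed-neighbor graph with node kinds
    (seed / connector / leaf) and a deterministic sorted edge list."""
    seeds = sorted(merged)
    if len(seeds) < 2:
        raise ValueError("need at least two seed genes")
    membership: dict[str, set[str]] = {}
    for seed in seeds:
        for nb in merged[seed]:
            membership.setdefault(nb.upper(), set()).add(seed)
    seed_set = set(seeds)
    connector_degree = {nb: len(owners)
                        for nb, owners in membership.items()
                        if nb not in seed_set and len(owners) >= min_degree}

    graph = nx.Graph()
    for seed in seeds:
        graph.add_node(seed, kind="seed")
    edges = []
    for nb, owners in membership.items():
        if nb not in seed_set:
            kind = "connector" if nb in connector_degree else "leaf"
            graph.add_node(nb, kind=kind)
        for seed in owners:
            if nb == seed:
                continue  # self-listing carries no edge
            edges.append((seed, nb))
            graph.add_edge(seed, nb)
    edges.sort()
    return ConnectorNetwork(graph=graph, connector_degree=connector_degree,
                            edges=edges)
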