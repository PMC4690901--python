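"""Two-mode and one-mode network measures.

Measures follow the conventions of small-scale social network analysis of
store–supplier ties:

* degree centrality of a store = its supplier connections, normalized by
  the number of suppliers realized in the same network (a percentage);
* the network core = the minimal set of highest-degree suppliers whose
  incident edges cover at least 80% of the network's edges;
* diversity = number of distinct supplier categories a store reaches;
* the one-mode projection links two stores iff they share >= 1 supplier,
  weighted by the shared-supplier count;
* density of the projection = percentage of store pairs sharing a supplier
  (weights dichotomized, isolated stores kept in the denominator).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_model import (
    BipartiteNetwork,
    CentralityTable,
    CoreResult,
    DataError,
    OneModeNetwork,
    SharedStats,
    Supplier,
    UsageError,
)

__all__ = [
    "degree_centrality",
    "extract_core",
    "diversity",
    "diversity_table",
    "project_one_mode",
    "density",
    "shared_stats",
]


def degree_centrality(network: BipartiteNetwork) -> CentralityTable:
    """Raw and normalized degree centrality for every store.

    All stores appear, including degree-0 isolates.  Normalization is
    100 × degree / (number of suppliers in this network); with zero
    suppliers the normalized column is NaN and the table is flagged.
    """
    deg = network.store_degree()
    n_sup = len(network.supplier_nodes)
    rows = []
    for store_id in sorted(network.store_nodes):
        raw = deg[store_id]
        rows.append(
            {
                "store_id": store_id,
                "raw_degree": raw,
                "normalized_pct": (100.0 * raw / n_sup) if n_sup else float("nan"),
            }
        )
    table = pd.DataFrame(rows, columns=["store_id", "raw_degree", "normalized_pct"])
    return CentralityTable(
        mode=network.mode,
        table=table,
        n_suppliers=n_sup,
        normalized_defined=n_sup > 0,
    )


def extract_core(network: BipartiteNetwork, threshold: float = 0.80) -> CoreResult:
    """Extract the network core by cumulative edge coverage.

    Suppliers are ranked by degree descending (ties broken by id ascending
    for reproducibility); the core is the shortest prefix whose summed
    degrees reach ``threshold`` of the edge count.  Since each edge touches
    exactly one supplier, the prefix degree sum equals the number of edges
    covered.
    """
    if not (0.0 < threshold <= 1.0):
        raise UsageError(f"core threshold must be in (0, 1], got {threshold}")
    if network.n_edges == 0:
        raise DataError(f"{network.mode}: cannot extract a core from an empty network")
    deg = network.supplier_degree()
    ranked = sorted(deg, key=lambda u: (-deg[u], u))
    needed = threshold * network.n_edges
    covered = 0
    core: list[str] = []
    for u in ranked:
        core.append(u)
        covered += deg[u]
        if covered >= needed:
            break
    return CoreResult(
        mode=network.mode,
        ranked_suppliers=tuple(ranked),
        core_suppliers=frozenset(core),
        covered_edge_fraction=covered / network.n_edges,
        threshold=threshold,
    )


def diversity(
    network: BipartiteNetwork,
    store_id: str,
    suppliers: Sequence[Supplier] | Mapping[str, Supplier],
) -> int:
    """Number of distinct supplier categories among a store's neighbors."""
    by_id = (
        dict(suppliers)
        if isinstance(suppliers, Mapping)
        else {u.supplier_id: u for u in suppliers}
    )
    neighbors = network.neighbors_of_store(store_id)  # raises on unknown store
    return len({by_id[u].category for u in neighbors})


def diversity_table(
    network: BipartiteNetwork,
    suppliers: Sequence[Supplier] | Mapping[str, Supplier],
) -> pd.DataFrame:
    rows = [
        {"store_id": s, "n_categories": diversity(network, s, suppliers)}
        for s in sorted(network.store_nodes)
    ]
    return pd.DataFrame(rows, columns=["store_id", "n_categories"])


def project_one_mode(network: BipartiteNetwork) -> OneModeNetwork:
    """Project the two-mode network onto stores.

    Two stores are adjacent iff they share >= 1 supplier; the edge weight is
    the shared-supplier count.  Isolated stores are kept as nodes.
    """
    if not network.supplier_nodes:
        return OneModeNetwork(store_nodes=network.store_nodes, weights={})
    g = network.to_networkx()
    proj = nx.bipartite.weighted_projected_graph(g, sorted(network.store_nodes))
    weights = {
        tuple(sorted((a, b))): int(data["weight"])
        for a, b, data in proj.edges(data=True)
    }
    return OneModeNetwork(store_nodes=network.store_nodes, weights=weights)


def density(one_mode: OneModeNetwork) -> float:
    """Percentage of store pairs sharing at least one supplier.

    Weights are dichotomized; isolated stores remain in the denominator.
    """
    n = len(one_mode.store_nodes)
    if n < 2:
        raise UsageError(f"density undefined for {n} store(s); need >= 2")
    possible = n * (n - 1) / 2
    return 100.0 * one_mode.n_edges / possible


def shared_stats(one_mode: OneModeNetwork) -> SharedStats:
    """Mean/min/max of positive shared-supplier counts, and isolate count."""
    weights = list(one_mode.weights.values())
    n_isolates = sum(1 for d in one_mode.degree().values() if d == 0)
    if not weights:
        return SharedStats(
            mean_shared=float("nan"), min_shared=None, max_shared=None,
            n_isolates=n_isolates,
        )
    return SharedStats(
        mean_shared=sum(weights) / len(weights),
        min_shared=min(weights),
        max_shared=max(weights),
        n_isolates=n_isolates,
    )
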