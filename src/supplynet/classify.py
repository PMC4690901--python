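"""Healthy vs. unhealthy classification and bipartite network construction.

A supplier enters a store's healthy supplier network (HSN) if the store
reports at least one promoted-food purchase there, and the unhealthy
supplier network (UHSN) if at least one purchase of an item higher in salt,
fat or sugar; the two classifications are not mutually exclusive.  Items
absent from the promoted-food catalog are reported, never silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_model import (
    BipartiteNetwork,
    ConfigurationError,
    Dataset,
    FoodCatalog,
    PurchaseRecord,
    Store,
    Supplier,
    CATEGORIES,
)

__all__ = [
    "classify_item",
    "build_networks",
    "RosterSummary",
    "roster_summary",
    "total_distinct_suppliers",
    "combined_category_counts",
    "filter_delivering",
    "unknown_items_frame",
]


def classify_item(item_name: str, catalog: FoodCatalog) -> str:
    """Classify one item as 'healthy', 'unhealthy' or 'unknown'.

    Lookup is deterministic after canonicalization (trim, collapse internal
    whitespace, lowercase).
    """
    if len(catalog) == 0:
        raise ConfigurationError("cannot classify against an empty catalog")
    return catalog.food_class(item_name)


def build_networks(
    purchases: Sequence[PurchaseRecord],
    catalog: FoodCatalog,
    stores: Sequence[Store],
    suppliers: Sequence[Supplier],
) -> tuple[BipartiteNetwork, BipartiteNetwork, list[PurchaseRecord]]:
    """Build the HSN and UHSN from a purchase table.

    Edge (store, supplier) exists in the HSN iff the store has >= 1
    healthy-classified purchase from that supplier, and in the UHSN iff
    >= 1 unhealthy-classified purchase; a supplier may appear in both.
    Returns ``(hsn, uhsn, unknown_purchases)`` where the last element lists
    purchases whose item is not in the catalog (they contribute to neither
    network).
    """
    store_ids = [s.store_id for s in stores]
    healthy_edges: set[tuple[str, str]] = set()
    unhealthy_edges: set[tuple[str, str]] = set()
    unknown: list[PurchaseRecord] = []
    for p in purchases:
        cls = classify_item(p.item_name, catalog)
        if cls == "healthy":
            healthy_edges.add((p.store_id, p.supplier_id))
        elif cls == "unhealthy":
            unhealthy_edges.add((p.store_id, p.supplier_id))
        else:
            unknown.append(p)
    hsn = BipartiteNetwork.from_edges("HSN", store_ids, healthy_edges)
    uhsn = BipartiteNetwork.from_edges("UHSN", store_ids, unhealthy_edges)
    return hsn, uhsn, unknown


def build_networks_from_dataset(
    dataset: Dataset,
) -> tuple[BipartiteNetwork, BipartiteNetwork, list[PurchaseRecord]]:
    return build_networks(
        dataset.purchases, dataset.catalog, dataset.stores, dataset.suppliers
    )


@dataclass(frozen=True)
class RosterSummary:
    """Supplier-roster counts for one network under both counting conventions.

    ``n_suppliers_entries`` expands multiplicity annotations (a roster line
    like "Name (2)" counts twice); ``n_suppliers_distinct`` collapses by
    name.  The published counts use both conventions, so both are reported.
    """

    mode: str
    n_suppliers_entries: int
    n_suppliers_distinct: int
    per_category_entries: dict[str, int]
    per_category_distinct: dict[str, int]
    overlap_with_other_mode: int


def _suppliers_in(network: BipartiteNetwork) -> frozenset[str]:
    return network.supplier_nodes


def roster_summary(
    network: BipartiteNetwork,
    other_network: BipartiteNetwork,
    suppliers: Sequence[Supplier] | Mapping[str, Supplier],
) -> RosterSummary:
    """Count a network's supplier roster under both conventions.

    ``overlap_with_other_mode`` is the number of distinct supplier
    identities present in both networks.
    """
    by_id = (
        dict(suppliers)
        if isinstance(suppliers, Mapping)
        else {u.supplier_id: u for u in suppliers}
    )
    ids = _suppliers_in(network)
    missing = sorted(ids - set(by_id))
    if missing:
        raise ConfigurationError(f"suppliers absent from the roster table: {missing}")
    per_entries: Counter = Counter()
    per_distinct: Counter = Counter()
    for sid in ids:
        u = by_id[sid]
        per_entries[u.category] += u.multiplicity
        per_distinct[u.category] += 1
    overlap = len(ids & _suppliers_in(other_network))
    return RosterSummary(
        mode=network.mode,
        n_suppliers_entries=sum(per_entries.values()),
        n_suppliers_distinct=len(ids),
        per_category_entries={c: per_entries.get(c, 0) for c in CATEGORIES},
        per_category_distinct={c: per_distinct.get(c, 0) for c in CATEGORIES},
        overlap_with_other_mode=overlap,
    )


def total_distinct_suppliers(
    net_a: BipartiteNetwork, net_b: BipartiteNetwork
) -> int:
    """Distinct supplier identities across both rosters (union by id)."""
    return len(_suppliers_in(net_a) | _suppliers_in(net_b))


def combined_category_counts(
    net_a: BipartiteNetwork,
    net_b: BipartiteNetwork,
    suppliers: Sequence[Supplier] | Mapping[str, Supplier],
) -> dict[str, int]:
    """Distinct-name supplier counts per category over the union of both
    rosters — the convention behind the published per-category totals."""
    by_id = (
        dict(suppliers)
        if isinstance(suppliers, Mapping)
        else {u.supplier_id: u for u in suppliers}
    )
    union = _suppliers_in(net_a) | _suppliers_in(net_b)
    counts: Counter = Counter(by_id[sid].category for sid in union)
    return {c: counts.get(c, 0) for c in CATEGORIES}


def filter_delivering(
    purchases: Sequence[PurchaseRecord],
    suppliers: Sequence[Supplier] | Mapping[str, Supplier],
) -> list[PurchaseRecord]:
    """Keep only purchases from suppliers that do NOT deliver.

    This is the sensitivity-analysis filter: connections sustained by
    delivery convenience are removed, leaving self-supply relationships.
    """
    by_id = (
        dict(suppliers)
        if isinstance(suppliers, Mapping)
        else {u.supplier_id: u for u in suppliers}
    )
    return [p for p in purchases if not by_id[p.supplier_id].delivers]


def unknown_items_frame(unknown: Sequence[PurchaseRecord]) -> pd.DataFrame:
    """Tidy report of purchases that could not be classified."""
    return pd.DataFrame(
        [
            {"store_id": p.store_id, "supplier_id": p.supplier_id, "item_name": p.item_name}
            for p in unknown
        ],
        columns=["store_id", "supplier_id", "item_name"],
    )
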