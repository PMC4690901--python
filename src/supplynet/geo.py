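"""Great-circle distances from stores to their connected suppliers.

Suppliers may operate several distribution sites; each store is assigned
the site nearest to it, the assumption being that storeowners self-supply
from the closest outlet.  Distances are haversine great-circle kilometres —
a desk-scale stand-in for GIS road distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_model import BipartiteNetwork, DataError, Store, Supplier

__all__ = ["EARTH_RADIUS_KM", "haversine_km", "DistanceTable", "store_supplier_distances"]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def _check_coords(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0):
        raise DataError(f"latitude {lat} out of [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        raise DataError(f"longitude {lon} out of [-180, 180]")


def haversine_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between two (latitude, longitude) points."""
    lat1, lon1 = p1
    lat2, lon2 = p2
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


@dataclass
class DistanceTable:
    """Per-edge nearest-site distances and per-store means.

    ``per_edge`` columns: store_id, supplier_id, km, site_index.
    ``per_store`` columns: store_id, mean_km (mean over the store's
    connected suppliers in the analysed network; NaN for isolates).
    """

    per_edge: pd.DataFrame
    per_store: pd.DataFrame

    def mean_km(self) -> dict[str, float]:
        return dict(zip(self.per_store["store_id"], self.per_store["mean_km"]))


def store_supplier_distances(
    stores: Sequence[Store],
    suppliers: Sequence[Supplier] | Mapping[str, Supplier],
    network: BipartiteNetwork,
) -> DistanceTable:
    """Nearest-site distance for every edge, plus per-store means.

    Raises :class:`DataError` naming any connected supplier with no sites.
    """
    by_id = (
        dict(suppliers)
        if isinstance(suppliers, Mapping)
        else {u.supplier_id: u for u in suppliers}
    )
    store_by_id = {s.store_id: s for s in stores}
    siteless = sorted(
        u for u in network.supplier_nodes if not by_id[u].sites
    )
    if siteless:
        raise DataError(
            f"connected supplier(s) with no distribution sites: {siteless}"
        )
    rows = []
    for s_id, u_id in sorted(network.edges):
        store = store_by_id[s_id]
        best_km, best_idx = math.inf, -1
        for idx, site in enumerate(by_id[u_id].sites):
            km = haversine_km(store.location, site)
            if km < best_km:
                best_km, best_idx = km, idx
        rows.append(
            {"store_id": s_id, "supplier_id": u_id, "km": best_km, "site_index": best_idx}
        )
    per_edge = pd.DataFrame(rows, columns=["store_id", "supplier_id", "km", "site_index"])
    means = []
    for s_id in sorted(network.store_nodes):
        sub = per_edge[per_edge["store_id"] == s_id]["km"]
        means.append(
            {"store_id": s_id, "mean_km": float(sub.mean()) if len(sub) else float("nan")}
        )
    per_store = pd.DataFrame(means, columns=["store_id", "mean_km"])
    return DistanceTable(per_edge=per_edge, per_store=per_store)
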