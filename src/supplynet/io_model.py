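"""Domain types and tabular/graph I/O for corner-store supplier networks.

The data model mirrors the survey instruments of a store-level food
procurement study: 24 urban corner stores report, per supplier, which food
and beverage items they acquire there.  Three tables (stores, suppliers,
purchases) plus a promoted-food catalog are the raw inputs; the analysis
modules build mode-labelled bipartite networks from them.

CSV schemas
-----------
stores.csv
    store_id, accepts_wic, accepts_snap, owner_ethnicity,
    years_current_store, years_any_store, customers_per_day,
    n_nonfamily_employees, n_family_employees, latitude, longitude
suppliers.csv
    supplier_id, name, category, delivers, multiplicity, sites
    (sites: semicolon-separated "lat,lon" pairs, may be empty)
purchases.csv
    store_id, supplier_id, item_name[, monthly_frequency, via_delivery]
catalog.csv
    item_name, food_class[, healthy_subclass]
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "SupplyNetError",
    "SchemaError",
    "IntegrityError",
    "DataError",
    "UsageError",
    "ConfigurationError",
    "ETHNICITIES",
    "CATEGORIES",
    "HEALTHY_SUBCLASSES",
    "canonical_item",
    "Store",
    "Supplier",
    "PurchaseRecord",
    "FoodCatalog",
    "Dataset",
    "BipartiteNetwork",
    "OneModeNetwork",
    "CoreResult",
    "CentralityTable",
    "SharedStats",
    "TTestResult",
    "RegressionResult",
    "load_dataset",
    "write_dataset",
    "export_graph",
    "import_graph",
]


# ---------------------------------------------------------------------------
# Errors


class SupplyNetError(Exception):
    """Base class for all package errors."""


class SchemaError(SupplyNetError):
    """A CSV is missing a required column or a field cannot be parsed."""


class IntegrityError(SupplyNetError):
    """Referential integrity or uniqueness violated across tables."""


class DataError(SupplyNetError):
    """Valid schema but scientifically unusable values."""


class UsageError(SupplyNetError):
    """An operation was called with out-of-contract arguments."""


class ConfigurationError(SupplyNetError):
    """A configuration object is internally inconsistent."""


# ---------------------------------------------------------------------------
# Enumerations

ETHNICITIES = ("african_american", "asian_hispanic")

# Standard Industrial Classification food-store groups observed in the study.
CATEGORIES = (
    "wholesale_club",
    "snacks",
    "specialty_foods",
    "beverages",
    "supermarket_grocery",
    "discount_department",
    "meat_market",
)

HEALTHY_SUBCLASSES = (
    "lower_calorie_beverage",
    "healthier_essential",
    "healthier_snack",
)


def canonical_item(name: str) -> str:
    """Canonicalize a free-text item name: trim, collapse whitespace, lowercase."""
    return " ".join(str(name).split()).lower()


# ---------------------------------------------------------------------------
# Entities


@dataclass(frozen=True)
class Store:
    """One corner store with the covariates used in the bivariate analysis."""

    store_id: str
    accepts_wic: bool
    accepts_snap: bool
    owner_ethnicity: str
    years_current_store: float
    years_any_store: float
    customers_per_day: float
    n_nonfamily_employees: float
    n_family_employees: float
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if self.owner_ethnicity not in ETHNICITIES:
            raise DataError(
                f"store {self.store_id!r}: owner_ethnicity must be one of "
                f"{ETHNICITIES}, got {self.owner_ethnicity!r}"
            )
        if not (-90.0 <= self.latitude <= 90.0):
            raise DataError(f"store {self.store_id!r}: latitude out of range")
        if not (-180.0 <= self.longitude <= 180.0):
            raise DataError(f"store {self.store_id!r}: longitude out of range")
        for attr in (
            "years_current_store",
            "years_any_store",
            "customers_per_day",
            "n_nonfamily_employees",
            "n_family_employees",
        ):
            v = getattr(self, attr)
            if not (v >= 0) or math.isnan(v):
                raise DataError(f"store {self.store_id!r}: {attr} must be >= 0")

    @property
    def location(self) -> tuple[float, float]:
        return (self.latitude, self.longitude)


@dataclass(frozen=True)
class Supplier:
    """A supplier identity: SIC category, delivery flag, distribution sites.

    ``multiplicity`` carries roster annotations such as "Name (2)" in the
    published supplier roster, where one identity stands for two distribution
    outlets; it only affects entry-convention roster counts.
    """

    supplier_id: str
    name: str
    category: str
    delivers: bool
    sites: tuple[tuple[float, float], ...] = ()
    multiplicity: int = 1
    note: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise DataError(
                f"supplier {self.supplier_id!r}: category must be one of "
                f"{CATEGORIES}, got {self.category!r}"
            )
        if self.multiplicity < 1:
            raise DataError(f"supplier {self.supplier_id!r}: multiplicity must be >= 1")
        for lat, lon in self.sites:
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                raise DataError(
                    f"supplier {self.supplier_id!r}: site ({lat}, {lon}) out of range"
                )


@dataclass(frozen=True)
class PurchaseRecord:
    """One store acquiring one item from one supplier — the evidence for an edge."""

    store_id: str
    supplier_id: str
    item_name: str
    monthly_frequency: int = 1
    via_delivery: bool = False

    def __post_init__(self) -> None:
        if not str(self.item_name).strip():
            raise DataError(
                f"purchase ({self.store_id!r}, {self.supplier_id!r}): empty item_name"
            )
        if self.monthly_frequency < 0:
            raise DataError(
                f"purchase ({self.store_id!r}, {self.supplier_id!r}): "
                "monthly_frequency must be >= 0"
            )


class FoodCatalog:
    """Promoted-food catalog: canonical item name -> healthy / unhealthy.

    Healthy items carry a subclass tag (lower-calorie beverage, healthier
    essential, healthier snack).  Lookup is case- and whitespace-insensitive.
    """

    def __init__(
        self,
        classes: Mapping[str, str],
        subclasses: Mapping[str, str] | None = None,
    ) -> None:
        self._classes: dict[str, str] = {}
        self._subclasses: dict[str, str] = {}
        subclasses = subclasses or {}
        for raw, cls in classes.items():
            item = canonical_item(raw)
            if cls not in ("healthy", "unhealthy"):
                raise DataError(f"catalog item {raw!r}: class must be healthy/unhealthy")
            if item in self._classes and self._classes[item] != cls:
                raise DataError(f"catalog item {raw!r} maps to both classes")
            self._classes[item] = cls
        for raw, sub in subclasses.items():
            item = canonical_item(raw)
            if sub:
                if sub not in HEALTHY_SUBCLASSES:
                    raise DataError(
                        f"catalog item {raw!r}: unknown healthy subclass {sub!r}"
                    )
                if self._classes.get(item) != "healthy":
                    raise DataError(
                        f"catalog item {raw!r}: subclass on a non-healthy item"
                    )
                self._subclasses[item] = sub

    def __len__(self) -> int:
        return len(self._classes)

    def __contains__(self, item: str) -> bool:
        return canonical_item(item) in self._classes

    def food_class(self, item: str) -> str:
        """Return 'healthy', 'unhealthy', or 'unknown' for an item name."""
        return self._classes.get(canonical_item(item), "unknown")

    def healthy_subclass(self, item: str) -> str | None:
        return self._subclasses.get(canonical_item(item))

    def items(self) -> Iterable[tuple[str, str]]:
        return self._classes.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "item_name": item,
                "food_class": cls,
                "healthy_subclass": self._subclasses.get(item, ""),
            }
            for item, cls in sorted(self._classes.items())
        ]
        return pd.DataFrame(rows, columns=["item_name", "food_class", "healthy_subclass"])


@dataclass
class Dataset:
    """A validated (stores, suppliers, purchases, catalog) bundle."""

    stores: list[Store]
    suppliers: list[Supplier]
    purchases: list[PurchaseRecord]
    catalog: FoodCatalog

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        store_ids = [s.store_id for s in self.stores]
        if len(set(store_ids)) != len(store_ids):
            dupes = sorted({i for i in store_ids if store_ids.count(i) > 1})
            raise IntegrityError(f"duplicate store_id(s): {dupes}")
        sup_ids = [u.supplier_id for u in self.suppliers]
        if len(set(sup_ids)) != len(sup_ids):
            dupes = sorted({i for i in sup_ids if sup_ids.count(i) > 1})
            raise IntegrityError(f"duplicate supplier_id(s): {dupes}")
        names = [u.name for u in self.suppliers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise IntegrityError(f"duplicate supplier name(s): {dupes}")
        known_stores = set(store_ids)
        known_sups = set(sup_ids)
        offenders = [
            (i, p.store_id, p.supplier_id)
            for i, p in enumerate(self.purchases)
            if p.store_id not in known_stores or p.supplier_id not in known_sups
        ]
        if offenders:
            raise IntegrityError(
                "purchases referencing unknown store/supplier (row, store_id, "
                f"supplier_id): {offenders[:10]}"
            )

    @property
    def store_ids(self) -> list[str]:
        return [s.store_id for s in self.stores]

    def store_by_id(self) -> dict[str, Store]:
        return {s.store_id: s for s in self.stores}

    def supplier_by_id(self) -> dict[str, Supplier]:
        return {u.supplier_id: u for u in self.suppliers}


# ---------------------------------------------------------------------------
# Network containers


@dataclass(frozen=True)
class BipartiteNetwork:
    """A mode-labelled two-mode store–supplier graph.

    ``mode`` is "HSN" (healthy supplier network) or "UHSN" (unhealthy).
    ``supplier_nodes`` holds exactly the suppliers with >= 1 edge;
    ``store_nodes`` holds every store in the dataset, so isolated stores
    (degree 0) remain visible to the centrality and density calculations.
    """

    mode: str
    store_nodes: frozenset[str]
    supplier_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.mode not in ("HSN", "UHSN"):
            raise UsageError(f"mode must be 'HSN' or 'UHSN', got {self.mode!r}")
        realized = frozenset(u for _, u in self.edges)
        if realized != self.supplier_nodes:
            raise IntegrityError(
                f"{self.mode}: supplier_nodes must be exactly the suppliers with "
                ">= 1 edge"
            )
        bad = [(s, u) for s, u in self.edges if s not in self.store_nodes]
        if bad:
            raise IntegrityError(f"{self.mode}: edge endpoints outside store set: {bad[:5]}")

    @classmethod
    def from_edges(
        cls, mode: str, store_ids: Iterable[str], edges: Iterable[tuple[str, str]]
    ) -> "BipartiteNetwork":
        e = frozenset((str(s), str(u)) for s, u in edges)
        return cls(
            mode=mode,
            store_nodes=frozenset(str(s) for s in store_ids),
            supplier_nodes=frozenset(u for _, u in e),
            edges=e,
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def store_degree(self) -> dict[str, int]:
        deg = {s: 0 for s in self.store_nodes}
        for s, _ in self.edges:
            deg[s] += 1
        return deg

    def supplier_degree(self) -> dict[str, int]:
        deg = {u: 0 for u in self.supplier_nodes}
        for _, u in self.edges:
            deg[u] += 1
        return deg

    def neighbors_of_store(self, store_id: str) -> frozenset[str]:
        if store_id not in self.store_nodes:
            raise UsageError(f"unknown store {store_id!r} in {self.mode}")
        return frozenset(u for s, u in self.edges if s == store_id)

    def to_networkx(
        self,
        suppliers: Mapping[str, Supplier] | None = None,
        core: frozenset[str] | set[str] | None = None,
    ) -> nx.Graph:
        g = nx.Graph(mode=self.mode)
        for s in sorted(self.store_nodes):
            g.add_node(s, role="store", bipartite=0)
        for u in sorted(self.supplier_nodes):
            attrs: dict = {"role": "supplier", "bipartite": 1}
            if suppliers is not None and u in suppliers:
                attrs["category"] = suppliers[u].category
                attrs["name"] = suppliers[u].name
            if core is not None:
                attrs["core"] = u in core
            g.add_node(u, **attrs)
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass(frozen=True)
class OneModeNetwork:
    """Store–store projection: weight = number of shared suppliers (>= 1)."""

    store_nodes: frozenset[str]
    weights: Mapping[tuple[str, str], int]  # keys sorted pairs

    def __post_init__(self) -> None:
        for (a, b), w in self.weights.items():
            if a == b:
                raise IntegrityError(f"self-loop on {a!r}")
            if (a, b) != tuple(sorted((a, b))):
                raise IntegrityError(f"edge key {(a, b)!r} not in sorted order")
            if a not in self.store_nodes or b not in self.store_nodes:
                raise IntegrityError(f"edge {(a, b)!r} endpoint outside store set")
            if w < 1:
                raise IntegrityError(f"edge {(a, b)!r} weight must be >= 1, got {w}")

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def degree(self) -> dict[str, int]:
        deg = {s: 0 for s in self.store_nodes}
        for a, b in self.weights:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for s in sorted(self.store_nodes):
            g.add_node(s, role="store")
        for (a, b), w in sorted(self.weights.items()):
            g.add_edge(a, b, weight=int(w))
        return g


# ---------------------------------------------------------------------------
# Result containers


@dataclass(frozen=True)
class CoreResult:
    """Coverage-rule network core: the minimal prefix of suppliers, ranked by
    degree, whose incident edges cover at least ``threshold`` of all edges."""

    mode: str
    ranked_suppliers: tuple[str, ...]
    core_suppliers: frozenset[str]
    covered_edge_fraction: float
    threshold: float

    @property
    def size(self) -> int:
        return len(self.core_suppliers)


@dataclass
class CentralityTable:
    """Per-store two-mode degree centrality for one network mode.

    ``table`` columns: store_id, raw_degree, normalized_pct.  The
    normalization denominator is the number of suppliers realized in the
    same network; when that is zero, ``normalized_defined`` is False and the
    normalized column is NaN.
    """

    mode: str
    table: pd.DataFrame
    n_suppliers: int
    normalized_defined: bool = True

    def raw(self) -> pd.Series:
        return self.table.set_index("store_id")["raw_degree"]

    def normalized(self) -> pd.Series:
        if not self.normalized_defined:
            raise UsageError(
                f"{self.mode}: normalized centrality undefined (no suppliers)"
            )
        return self.table.set_index("store_id")["normalized_pct"]

    def values(self, outcome_scale: str) -> pd.Series:
        if outcome_scale == "raw_degree":
            return self.raw()
        if outcome_scale == "normalized_pct":
            return self.normalized()
        raise UsageError(f"unknown outcome_scale {outcome_scale!r}")


@dataclass(frozen=True)
class SharedStats:
    """Shared-supplier summary of a one-mode projection."""

    mean_shared: float
    min_shared: int | None
    max_shared: int | None
    n_isolates: int


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p: float
    group_means: tuple[float, float]
    ci_95: tuple[float, float]
    method: str
    degenerate: bool = False
    note: str = ""


@dataclass(frozen=True)
class RegressionResult:
    covariate: str
    b: float
    ci_95: tuple[float, float]
    p: float
    n: int
    outcome_scale: str
    degenerate: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# Tabular I/O

_STORE_COLUMNS = [
    "store_id",
    "accepts_wic",
    "accepts_snap",
    "owner_ethnicity",
    "years_current_store",
    "years_any_store",
    "customers_per_day",
    "n_nonfamily_employees",
    "n_family_employees",
    "latitude",
    "longitude",
]
_SUPPLIER_COLUMNS = ["supplier_id", "name", "category", "delivers", "sites"]
_PURCHASE_COLUMNS = ["store_id", "supplier_id", "item_name"]
_CATALOG_COLUMNS = ["item_name", "food_class"]

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _parse_bool(value, *, context: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise SchemaError(f"{context}: cannot parse boolean from {value!r}")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_sites(raw: str, *, context: str) -> tuple[tuple[float, float], ...]:
    s = str(raw).strip()
    if not s or s.lower() == "nan":
        return ()
    sites = []
    for part in s.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            lat_s, lon_s = part.split(",")
            sites.append((float(lat_s), float(lon_s)))
        except ValueError as exc:
            raise SchemaError(f"{context}: cannot parse site {part!r}") from exc
    return tuple(sites)


def read_stores(path: str | os.PathLike) -> list[Store]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _STORE_COLUMNS, str(path))
    stores = []
    for i, row in df.iterrows():
        ctx = f"{path} row {i}"
        try:
            stores.append(
                Store(
                    store_id=row["store_id"].strip(),
                    accepts_wic=_parse_bool(row["accepts_wic"], context=ctx),
                    accepts_snap=_parse_bool(row["accepts_snap"], context=ctx),
                    owner_ethnicity=row["owner_ethnicity"].strip(),
                    years_current_store=float(row["years_current_store"]),
                    years_any_store=float(row["years_any_store"]),
                    customers_per_day=float(row["customers_per_day"]),
                    n_nonfamily_employees=float(row["n_nonfamily_employees"]),
                    n_family_employees=float(row["n_family_employees"]),
                    latitude=float(row["latitude"]),
                    longitude=float(row["longitude"]),
                )
            )
        except (ValueError, DataError) as exc:
            raise SchemaError(f"{ctx}: {exc}") from exc
    return stores


def read_suppliers(path: str | os.PathLike) -> list[Supplier]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _SUPPLIER_COLUMNS, str(path))
    suppliers = []
    for i, row in df.iterrows():
        ctx = f"{path} row {i}"
        try:
            suppliers.append(
                Supplier(
                    supplier_id=row["supplier_id"].strip(),
                    name=row["name"].strip(),
                    category=row["category"].strip(),
                    delivers=_parse_bool(row["delivers"], context=ctx),
                    sites=_parse_sites(row["sites"], context=ctx),
                    multiplicity=int(row["multiplicity"]) if "multiplicity" in df.columns and str(row["multiplicity"]).strip() else 1,
                    note=row["note"].strip() if "note" in df.columns else "",
                )
            )
        except (ValueError, DataError) as exc:
            raise SchemaError(f"{ctx}: {exc}") from exc
    return suppliers


def read_purchases(path: str | os.PathLike) -> list[PurchaseRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _PURCHASE_COLUMNS, str(path))
    purchases = []
    for i, row in df.iterrows():
        ctx = f"{path} row {i}"
        try:
            freq = row["monthly_frequency"] if "monthly_frequency" in df.columns else ""
            via = row["via_delivery"] if "via_delivery" in df.columns else ""
            purchases.append(
                PurchaseRecord(
                    store_id=row["store_id"].strip(),
                    supplier_id=row["supplier_id"].strip(),
                    item_name=canonical_item(row["item_name"]),
                    monthly_frequency=int(freq) if str(freq).strip() else 1,
                    via_delivery=_parse_bool(via, context=ctx),
                )
            )
        except (ValueError, DataError) as exc:
            raise SchemaError(f"{ctx}: {exc}") from exc
    return purchases


def read_catalog(path: str | os.PathLike) -> FoodCatalog:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _CATALOG_COLUMNS, str(path))
    classes: dict[str, str] = {}
    subclasses: dict[str, str] = {}
    for i, row in df.iterrows():
        item = canonical_item(row["item_name"])
        cls = row["food_class"].strip().lower()
        if item in classes and classes[item] != cls:
            raise DataError(f"{path} row {i}: item {item!r} maps to both classes")
        classes[item] = cls
        if "healthy_subclass" in df.columns and str(row["healthy_subclass"]).strip():
            subclasses[item] = row["healthy_subclass"].strip()
    return FoodCatalog(classes, subclasses)


def load_dataset(
    store_path: str | os.PathLike,
    supplier_path: str | os.PathLike,
    purchase_path: str | os.PathLike,
    catalog_path: str | os.PathLike,
) -> Dataset:
    """Read and cross-validate the four input tables.

    Raises :class:`SchemaError` for missing columns or unparseable fields
    (naming the file, row and column), and :class:`IntegrityError` for
    dangling references or duplicate supplier names.
    """
    for p in (store_path, supplier_path, purchase_path, catalog_path):
        if not os.path.exists(p):
            raise SchemaError(f"input file not found: {p}")
    return Dataset(
        stores=read_stores(store_path),
        suppliers=read_suppliers(supplier_path),
        purchases=read_purchases(purchase_path),
        catalog=read_catalog(catalog_path),
    )


def _stores_frame(stores: Sequence[Store]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "store_id": s.store_id,
                "accepts_wic": s.accepts_wic,
                "accepts_snap": s.accepts_snap,
                "owner_ethnicity": s.owner_ethnicity,
                "years_current_store": s.years_current_store,
                "years_any_store": s.years_any_store,
                "customers_per_day": s.customers_per_day,
                "n_nonfamily_employees": s.n_nonfamily_employees,
                "n_family_employees": s.n_family_employees,
                "latitude": s.latitude,
                "longitude": s.longitude,
            }
            for s in stores
        ],
        columns=_STORE_COLUMNS,
    )


def _suppliers_frame(suppliers: Sequence[Supplier]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "supplier_id": u.supplier_id,
                "name": u.name,
                "category": u.category,
                "delivers": u.delivers,
                "sites": ";".join(f"{lat!r},{lon!r}" for lat, lon in u.sites),
                "multiplicity": u.multiplicity,
                "note": u.note,
            }
            for u in suppliers
        ],
        columns=_SUPPLIER_COLUMNS + ["multiplicity", "note"],
    )


def _purchases_frame(purchases: Sequence[PurchaseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "store_id": p.store_id,
                "supplier_id": p.supplier_id,
                "item_name": p.item_name,
                "monthly_frequency": p.monthly_frequency,
                "via_delivery": p.via_delivery,
            }
            for p in purchases
        ],
        columns=_PURCHASE_COLUMNS + ["monthly_frequency", "via_delivery"],
    )


def write_dataset(dataset: Dataset, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the four tables as CSV under ``out_dir``; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "stores": os.path.join(out_dir, "stores.csv"),
        "suppliers": os.path.join(out_dir, "suppliers.csv"),
        "purchases": os.path.join(out_dir, "purchases.csv"),
        "catalog": os.path.join(out_dir, "catalog.csv"),
    }
    _stores_frame(dataset.stores).to_csv(paths["stores"], index=False)
    _suppliers_frame(dataset.suppliers).to_csv(paths["suppliers"], index=False)
    _purchases_frame(dataset.purchases).to_csv(paths["purchases"], index=False)
    dataset.catalog.to_frame().to_csv(paths["catalog"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Graph export

GRAPH_FORMATS = ("graphml", "edgelist_csv")


def export_graph(
    network: BipartiteNetwork | OneModeNetwork,
    path: str | os.PathLike,
    fmt: str = "graphml",
    *,
    suppliers: Mapping[str, Supplier] | None = None,
    core: frozenset[str] | set[str] | None = None,
) -> None:
    """Serialize a network for external viewers.

    GraphML keeps every node/edge attribute (role, category, core flag,
    weight).  ``edgelist_csv`` writes source,target,weight rows; isolated
    nodes are kept as rows with an empty target so re-import reproduces the
    node set exactly.
    """
    if fmt not in GRAPH_FORMATS:
        raise UsageError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")
    if isinstance(network, BipartiteNetwork):
        g = network.to_networkx(suppliers=suppliers, core=core)
    elif isinstance(network, OneModeNetwork):
        g = network.to_networkx()
    else:
        raise UsageError(f"cannot export object of type {type(network).__name__}")
    if fmt == "graphml":
        nx.write_graphml(g, path)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        covered: set = set()
        for a, b, data in sorted(g.edges(data=True)):
            writer.writerow([a, b, data.get("weight", 1)])
            covered.update((a, b))
        for node in sorted(set(g.nodes) - covered):
            writer.writerow([node, "", ""])


def import_graph(path: str | os.PathLike, fmt: str = "graphml") -> nx.Graph:
    """Read a graph written by :func:`export_graph`."""
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt != "edgelist_csv":
        raise UsageError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")
    g = nx.Graph()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            if row["target"]:
                w = row["weight"]
                g.add_edge(row["source"], row["target"], weight=int(w) if w else 1)
            else:
                g.add_node(row["source"])
    return g
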