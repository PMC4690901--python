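"""Synthetic procurement datasets with the structure the analysis assumes.

The generator emulates the survey output of a 24-store corner-store sample:
42 suppliers in seven SIC categories, a dense unhealthy purchasing pattern,
a sparse healthy one, and store covariates whose effects on healthy-network
degree are configurable.  Ties are Bernoulli-independent given covariates;
each realized tie is witnessed by at least one catalogued purchase row.

Also packages the published supplier roster as a fixture
(:func:`make_paper_fixture`, :func:`fixture_dataset`).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._roster import ROSTER
from .io_model import (
    CATEGORIES,
    ConfigurationError,
    Dataset,
    FoodCatalog,
    PurchaseRecord,
    Store,
    Supplier,
)

__all__ = [
    "SyntheticConfig",
    "default_catalog",
    "generate",
    "make_paper_fixture",
    "fixture_dataset",
]


# ---------------------------------------------------------------------------
# Promoted-food catalog

_HEALTHY_ITEMS = {
    "bottled water": "lower_calorie_beverage",
    "diet soda": "lower_calorie_beverage",
    "low-fat milk": "lower_calorie_beverage",
    "unsweetened iced tea": "lower_calorie_beverage",
    "whole wheat bread": "healthier_essential",
    "canned tuna in water": "healthier_essential",
    "frozen vegetables": "healthier_essential",
    "brown rice": "healthier_essential",
    "fresh fruit": "healthier_snack",
    "baked chips": "healthier_snack",
    "unsalted nuts": "healthier_snack",
    "low-fat yogurt": "healthier_snack",
}

_UNHEALTHY_ITEMS = (
    "chips",
    "candy",
    "soda",
    "fruit punch",
    "baked goods",
    "cookies",
    "ice cream",
    "energy drink",
    "snack cakes",
)


def default_catalog() -> FoodCatalog:
    """A compact promoted-food catalog in the three healthy classes, plus
    the usual corner-store unhealthy staples."""
    classes = {item: "healthy" for item in _HEALTHY_ITEMS}
    classes.update({item: "unhealthy" for item in _UNHEALTHY_ITEMS})
    return FoodCatalog(classes, dict(_HEALTHY_ITEMS))


# ---------------------------------------------------------------------------
# Configuration


def _default_category_counts() -> dict[str, int]:
    return {
        "wholesale_club": 11,
        "snacks": 10,
        "specialty_foods": 4,
        "beverages": 5,
        "supermarket_grocery": 9,
        "discount_department": 2,
        "meat_market": 1,
    }


def _default_healthy_menu_rates() -> dict[str, float]:
    # wholesalers / supermarkets / discount stores carry both menus;
    # snack suppliers occasionally carry a healthier line; beverage
    # manufacturers, specialty vendors and meat markets do not here
    return {
        "wholesale_club": 1.0,
        "supermarket_grocery": 1.0,
        "discount_department": 1.0,
        "snacks": 0.2,
        "specialty_foods": 0.0,
        "beverages": 0.0,
        "meat_market": 0.0,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Tie probabilities: every supplier carries an unhealthy menu and each
    (store, supplier) unhealthy tie is Bernoulli(``p_unhealthy_tie``).
    Healthy ties exist only toward suppliers with a healthy menu; the
    per-tie probability for store *i* is

        p_i = p_healthy_tie_base + (sum of that store's covariate effects) / H

    where H is the number of healthy-menu suppliers, so each effect shifts
    the store's *expected healthy degree* by the configured number of
    connections.  Probabilities are clamped to [0, 1] with a warning.
    """

    seed: int = 0
    n_stores: int = 24
    category_counts: dict[str, int] = field(default_factory=_default_category_counts)
    p_unhealthy_tie: float = 0.215
    p_healthy_tie_base: float = 0.117
    ethnicity_effect: float = -1.5  # expected healthy connections, asian_hispanic vs ref
    snap_effect: float = -1.9
    wic_effect: float = 0.0
    wic_rate: float = 0.458
    snap_rate: float = 0.917
    p_asian_hispanic: float = 0.79
    years_current_mean: float = 9.5
    years_current_sd: float = 7.7
    years_any_mean: float = 15.6
    years_any_sd: float = 9.1
    customers_mean: float = 165.0
    customers_sd: float = 145.2
    nonfamily_mean: float = 0.75
    family_mean: float = 1.96
    delivery_rate: float = 0.4
    bbox: tuple[float, float, float, float] = (39.20, 39.38, -76.72, -76.52)
    min_sites: int = 1
    max_sites: int = 3
    healthy_menu_rates: dict[str, float] = field(
        default_factory=_default_healthy_menu_rates
    )

    def validate(self) -> None:
        probs = {
            "p_unhealthy_tie": self.p_unhealthy_tie,
            "p_healthy_tie_base": self.p_healthy_tie_base,
            "wic_rate": self.wic_rate,
            "snap_rate": self.snap_rate,
            "p_asian_hispanic": self.p_asian_hispanic,
            "delivery_rate": self.delivery_rate,
            **{f"healthy_menu_rates[{c}]": r for c, r in self.healthy_menu_rates.items()},
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.n_stores < 1:
            raise ConfigurationError("n_stores must be >= 1")
        for c, k in self.category_counts.items():
            if c not in CATEGORIES:
                raise ConfigurationError(f"unknown category {c!r}")
            if k < 0:
                raise ConfigurationError(f"category count for {c!r} must be >= 0")
        if not (1 <= self.min_sites <= self.max_sites):
            raise ConfigurationError("need 1 <= min_sites <= max_sites")
        expected_healthy_capable = sum(
            self.category_counts.get(c, 0) * self.healthy_menu_rates.get(c, 0.0)
            for c in CATEGORIES
        )
        if self.p_healthy_tie_base > 0 and expected_healthy_capable == 0:
            raise ConfigurationError(
                "p_healthy_tie_base > 0 but no category can carry a healthy menu"
            )

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Generation


def _truncated_normal(rng, mean, sd, size) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size), 0.0, None)


def generate(config: SyntheticConfig | None = None) -> Dataset:
    """Draw one synthetic dataset; byte-identical under the same seed."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    lat_lo, lat_hi, lon_lo, lon_hi = config.bbox

    # --- stores -----------------------------------------------------------
    n = config.n_stores
    wic = rng.random(n) < config.wic_rate
    snap = rng.random(n) < config.snap_rate
    asian_hispanic = rng.random(n) < config.p_asian_hispanic
    years_any = _truncated_normal(rng, config.years_any_mean, config.years_any_sd, n)
    years_current = np.minimum(
        _truncated_normal(rng, config.years_current_mean, config.years_current_sd, n),
        years_any,
    )
    customers = np.round(_truncated_normal(rng, config.customers_mean, config.customers_sd, n))
    nonfamily = rng.poisson(config.nonfamily_mean, n)
    family = rng.poisson(config.family_mean, n)
    lats = rng.uniform(lat_lo, lat_hi, n)
    lons = rng.uniform(lon_lo, lon_hi, n)
    stores = [
        Store(
            store_id=f"store_{i + 1:02d}",
            accepts_wic=bool(wic[i]),
            accepts_snap=bool(snap[i]),
            owner_ethnicity="asian_hispanic" if asian_hispanic[i] else "african_american",
            years_current_store=float(years_current[i]),
            years_any_store=float(years_any[i]),
            customers_per_day=float(customers[i]),
            n_nonfamily_employees=float(nonfamily[i]),
            n_family_employees=float(family[i]),
            latitude=float(lats[i]),
            longitude=float(lons[i]),
        )
        for i in range(n)
    ]

    # --- suppliers --------------------------------------------------------
    suppliers: list[Supplier] = []
    healthy_menu: dict[str, bool] = {}
    k = 0
    for cat in CATEGORIES:
        for j in range(config.category_counts.get(cat, 0)):
            k += 1
            sid = f"sup_{k:02d}"
            n_sites = int(rng.integers(config.min_sites, config.max_sites + 1))
            sites = tuple(
                (float(rng.uniform(lat_lo, lat_hi)), float(rng.uniform(lon_lo, lon_hi)))
                for _ in range(n_sites)
            )
            suppliers.append(
                Supplier(
                    supplier_id=sid,
                    name=f"{cat.replace('_', ' ').title()} {j + 1}",
                    category=cat,
                    delivers=bool(rng.random() < config.delivery_rate),
                    sites=sites,
                )
            )
            healthy_menu[sid] = bool(rng.random() < config.healthy_menu_rates.get(cat, 0.0))

    healthy_capable = [u.supplier_id for u in suppliers if healthy_menu[u.supplier_id]]
    h = len(healthy_capable)
    if config.p_healthy_tie_base > 0 and h == 0:
        raise ConfigurationError(
            "no supplier drew a healthy menu although p_healthy_tie_base > 0; "
            "raise healthy_menu_rates or category counts"
        )

    # --- ties and purchases ----------------------------------------------
    healthy_items = sorted(_HEALTHY_ITEMS)
    unhealthy_items = sorted(_UNHEALTHY_ITEMS)
    catalog = default_catalog()
    purchases: list[PurchaseRecord] = []
    clamped = 0
    by_id = {u.supplier_id: u for u in suppliers}
    for i, store in enumerate(stores):
        effect = (
            config.ethnicity_effect * (store.owner_ethnicity == "asian_hispanic")
            + config.snap_effect * store.accepts_snap
            + config.wic_effect * store.accepts_wic
        )
        p_healthy = config.p_healthy_tie_base + (effect / h if h else 0.0)
        if not (0.0 <= p_healthy <= 1.0):
            clamped += 1
            p_healthy = min(1.0, max(0.0, p_healthy))
        for u in suppliers:
            if rng.random() < config.p_unhealthy_tie:
                purchases.append(
                    PurchaseRecord(
                        store_id=store.store_id,
                        supplier_id=u.supplier_id,
                        item_name=unhealthy_items[int(rng.integers(len(unhealthy_items)))],
                        monthly_frequency=1 + int(rng.poisson(2)),
                        via_delivery=u.delivers,
                    )
                )
            if healthy_menu[u.supplier_id] and rng.random() < p_healthy:
                purchases.append(
                    PurchaseRecord(
                        store_id=store.store_id,
                        supplier_id=u.supplier_id,
                        item_name=healthy_items[int(rng.integers(len(healthy_items)))],
                        monthly_frequency=1 + int(rng.poisson(2)),
                        via_delivery=u.delivers,
                    )
                )
    if clamped:
        warnings.warn(
            f"healthy-tie probability clamped to [0, 1] for {clamped} store(s); "
            "covariate effects exceed the feasible degree range",
            stacklevel=2,
        )
    return Dataset(stores=stores, suppliers=suppliers, purchases=purchases, catalog=catalog)


# ---------------------------------------------------------------------------
# Published-roster fixture


def make_paper_fixture() -> pd.DataFrame:
    """The published supplier roster as a tidy frame.

    Columns: name, category, in_uhsn, in_hsn, multiplicity, note.
    42 distinct supplier identities; the healthy roster expands to 15
    entries under the multiplicity convention, the unhealthy roster has
    41 distinct names.
    """
    return pd.DataFrame(
        list(ROSTER),
        columns=["name", "category", "in_uhsn", "in_hsn", "multiplicity", "note"],
    )


def fixture_dataset() -> Dataset:
    """The roster fixture as a loadable dataset.

    The store–supplier edge list behind the published rosters was never
    released, so membership is witnessed through a single pooled
    pseudo-store: one generic unhealthy purchase per unhealthy-roster
    supplier and one generic healthy purchase per healthy-roster supplier.
    Roster counts and category tallies are exact; store-level statistics
    are not meaningful on this fixture.
    """
    store = Store(
        store_id="pooled_store",
        accepts_wic=True,
        accepts_snap=True,
        owner_ethnicity="african_american",
        years_current_store=9.5,
        years_any_store=15.6,
        customers_per_day=165.0,
        n_nonfamily_employees=1.0,
        n_family_employees=2.0,
        latitude=39.2904,
        longitude=-76.6122,
    )
    suppliers = []
    purchases = []
    for idx, (name, cat, in_uhsn, in_hsn, mult, note) in enumerate(ROSTER):
        sid = f"roster_{idx + 1:02d}"
        suppliers.append(
            Supplier(
                supplier_id=sid,
                name=name,
                category=cat,
                delivers=False,
                sites=(),
                multiplicity=mult,
                note=note,
            )
        )
        if in_uhsn:
            purchases.append(PurchaseRecord(store.store_id, sid, "chips"))
        if in_hsn:
            purchases.append(PurchaseRecord(store.store_id, sid, "bottled water"))
    return Dataset(
        stores=[store], suppliers=suppliers, purchases=purchases, catalog=default_catalog()
    )
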