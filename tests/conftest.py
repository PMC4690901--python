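import pytest

from supplynet.io_model import (
    Dataset,
    FoodCatalog,
    PurchaseRecord,
    Store,
    Supplier,
)


def make_store(i: int, **overrides) -> Store:
    base = dict(
        store_id=f"s{i:02d}",
        accepts_wic=i % 2 == 0,
        accepts_snap=True,
        owner_ethnicity="asian_hispanic" if i % 3 else "african_american",
        years_current_store=5.0 + i,
        years_any_store=10.0 + i,
        customers_per_day=100.0 + 10 * i,
        n_nonfamily_employees=1.0,
        n_family_employees=2.0,
        latitude=39.29 + 0.001 * i,
        longitude=-76.61 - 0.001 * i,
    )
    base.update(overrides)
    return Store(**base)


def make_supplier(i: int, **overrides) -> Supplier:
    base = dict(
        supplier_id=f"u{i:02d}",
        name=f"Supplier {i}",
        category="wholesale_club",
        delivers=False,
        sites=((39.30 + 0.01 * i, -76.60),),
    )
    base.update(overrides)
    return Supplier(**base)


@pytest.fixture
def small_catalog() -> FoodCatalog:
    return FoodCatalog(
        {
            "bottled water": "healthy",
            "bananas": "healthy",
            "low-fat milk": "healthy",
            "chips": "unhealthy",
            "soda": "unhealthy",
            "candy": "unhealthy",
        },
        {"bottled water": "lower_calorie_beverage", "low-fat milk": "lower_calorie_beverage"},
    )


@pytest.fixture
def toy_dataset(small_catalog) -> Dataset:
    stores = [make_store(i) for i in range(1, 4)]
    suppliers = [
        make_supplier(1, category="wholesale_club"),
        make_supplier(2, category="supermarket_grocery", delivers=True),
        make_supplier(3, category="snacks"),
    ]
    purchases = [
        PurchaseRecord("s01", "u01", "bottled water"),
        PurchaseRecord("s01", "u01", "chips"),
        PurchaseRecord("s01", "u02", "soda"),
        PurchaseRecord("s02", "u01", "bananas"),
        PurchaseRecord("s02", "u03", "candy"),
        PurchaseRecord("s03", "u03", "chips"),
    ]
    return Dataset(stores=stores, suppliers=suppliers, purchases=purchases, catalog=small_catalog)
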