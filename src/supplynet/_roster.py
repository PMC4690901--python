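"""Published supplier roster: 42 distinct suppliers across 7 SIC categories.

Each row: (name, category, in_uhsn, in_hsn, multiplicity, note).
``multiplicity`` > 1 records a roster annotation where one supplier
identity stood for that many outlets in the healthy roster ("Name (2)").
Parenthetical descriptors such as "(ice cream)" are kept in ``note``.
"""

from __future__ import annotations

ROSTER: tuple[tuple[str, str, bool, bool, int, str], ...] = (
    # wholesale club
    ("B. Green Wholesale East", "wholesale_club", True, True, 1, ""),
    ("B. Green Wholesale West", "wholesale_club", True, True, 1, ""),
    ("BJ's Wholesale Club", "wholesale_club", True, True, 1, ""),
    ("Costco Wholesale", "wholesale_club", True, True, 1, ""),
    ("Eastern Food Services", "wholesale_club", True, False, 1, ""),
    ("George J. Falter Co.", "wholesale_club", True, False, 1, ""),
    ("Jetro Cash & Carry", "wholesale_club", True, True, 1, ""),
    ("LG Wholesale", "wholesale_club", True, False, 1, ""),
    ("Maryland Cash & Carry", "wholesale_club", True, True, 2, "two outlets in healthy roster"),
    ("Restaurant Depot", "wholesale_club", True, False, 1, ""),
    ("Sam's Club", "wholesale_club", True, True, 1, ""),
    # snacks
    ("Berliner Specialty Distributors", "snacks", True, False, 1, "ice cream"),
    ("Blue Bunny", "snacks", True, False, 1, "ice cream"),
    ("Brigg's Ice Cream Co.", "snacks", True, False, 1, ""),
    ("Frito Lay", "snacks", True, False, 1, ""),
    ("Herr's Snacks", "snacks", True, False, 1, ""),
    ("McKee Foods", "snacks", True, True, 1, ""),
    ("Raylicious", "snacks", True, False, 1, ""),
    ("Stone Creek Countrywide Snacks", "snacks", True, False, 1, ""),
    ("Tastykake", "snacks", True, False, 1, ""),
    ("Utz Quality Foods", "snacks", True, True, 1, ""),
    # other specialty foods
    ("Farmer's market", "specialty_foods", True, False, 1, ""),
    ("Hauswald Bakery", "specialty_foods", True, False, 1, ""),
    ("Sponseller's Egg Co.", "specialty_foods", True, False, 1, ""),
    ("Zeke's Coffee", "specialty_foods", True, False, 1, ""),
    # beverages
    ("Arizona Beverages USA", "beverages", True, False, 1, ""),
    ("Canada Dry", "beverages", True, False, 1, ""),
    ("Coca-Cola Company", "beverages", True, False, 1, ""),
    ("Everfresh Beverages", "beverages", True, False, 1, ""),
    ("PepsiCo", "beverages", True, False, 1, ""),
    # supermarket / grocery
    ("Food Depot", "supermarket_grocery", True, False, 1, ""),
    ("Giant Food Stores", "supermarket_grocery", True, True, 1, ""),
    ("Mars Supermarkets", "supermarket_grocery", True, False, 1, ""),
    ("Martin's Food Markets", "supermarket_grocery", True, False, 1, ""),
    ("Safeway", "supermarket_grocery", True, True, 1, ""),
    ("Save-A-Lot", "supermarket_grocery", True, True, 1, ""),
    ("Shoppers Foods and Pharmacy", "supermarket_grocery", True, False, 1, ""),
    ("Stop Shop and Save", "supermarket_grocery", True, False, 1, ""),
    ("Wegmans", "supermarket_grocery", False, True, 1, ""),
    # discount department store
    ("Dollar Mark", "discount_department", True, False, 1, ""),
    ("Walmart", "discount_department", True, True, 1, ""),
    # meat market
    ("Manger Packing Corporation", "meat_market", True, False, 1, ""),
)
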