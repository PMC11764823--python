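"""Food-item registry for the two study menus.

Thirteen food items spread over four meals (breakfast, lunch, snack,
dinner) compose two daily menus, A and B; yogurt appears in both.  Each
entry also records the number of raw 5 Hz records the original watches
collected for that item across all subjects and wrists, which pins the
overall shape of the study the synthetic generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FoodItem:
    food_id: str
    name: str
    meal: str
    menus: tuple[str, ...]
    raw_records: int


FOOD_REGISTRY: dict[str, FoodItem] = {
    f.food_id: f
    for f in (
        FoodItem("01", "Rusks and Jelly", "breakfast", ("A",), 15830),
        FoodItem("02", "Yogurt", "breakfast", ("A", "B"), 40114),
        FoodItem("03", "Croissant", "breakfast", ("B",), 9224),
        FoodItem("04", "Risotto", "lunch", ("A",), 32422),
        FoodItem("05", "Taglierini", "lunch", ("B",), 30458),
        FoodItem("06", "Mozzarella", "lunch", ("A",), 15450),
        FoodItem("07", "Meatballs", "lunch", ("B",), 11240),
        FoodItem("08", "Biscuits", "snack", ("A",), 22090),
        FoodItem("09", "Sandwich", "snack", ("B",), 17652),
        FoodItem("10", "Legume soup", "dinner", ("A",), 19034),
        FoodItem("11", "Artichoke and Chicken", "dinner", ("A",), 17984),
        FoodItem("12", "Parmigiana", "dinner", ("B",), 31436),
        FoodItem("13", "Stracchino", "dinner", ("B",), 15326),
    )
}

ALL_FOOD_IDS: tuple[str, ...] = tuple(sorted(FOOD_REGISTRY))

#: foods eaten moving both hands actively; for these the non-dominant
#: wrist carries the eating gesture too.
TWO_HANDED_FOODS = frozenset({"05", "06", "07", "09", "13"})

MEAL_ORDER = ("breakfast", "lunch", "snack", "dinner")


def menu_items(menu: str) -> list[str]:
    """Food ids of one menu, in meal order then id order (7 per menu)."""
    if menu not in ("A", "B"):
        raise ValueError(f"unknown menu {menu!r}; valid menus are A, B")
    items = [fid for fid, f in FOOD_REGISTRY.items() if menu in f.menus]
    return sorted(items, key=lambda fid: (MEAL_ORDER.index(FOOD_REGISTRY[fid].meal), fid))


def total_raw_records() -> int:
    """Sum of the per-food raw-record counts across the registry."""
    return sum(f.raw_records for f in FOOD_REGISTRY.values())
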