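"""Land-use/land-cover legend shared by all stages.

Integer codes for the LULC classes used throughout the pipeline, mirroring
the class list of the default resistance table (paddy field through rock).
Groupings (cropland, forest, water, built-up ...) are provided for the
habitat-suitability and sensitivity lookups, which operate on coarser
categories than the resistance table does.
"""

from __future__ import annotations

# code -> canonical class name
LULC_LEGEND: dict[int, str] = {
    1: "paddy_field",
    2: "irrigated_land",
    3: "forestland",
    4: "shrubland",
    5: "open_woodland",
    6: "other_forestland",
    7: "high_density_grassland",
    8: "middle_density_grassland",
    9: "low_density_grassland",
    10: "river",
    11: "lake",
    12: "pond",
    13: "beach_land",
    14: "urban_construction_land",
    15: "rural_construction_land",
    16: "mine",
    17: "swampland",
    18: "bare",
    19: "rock",
}

NAME_TO_CODE: dict[str, int] = {v: k for k, v in LULC_LEGEND.items()}

# coarse categories used by sensitivity scoring and habitat parameters
CROPLAND = frozenset({1, 2})
FOREST = frozenset({3, 4, 5, 6})
GRASSLAND = frozenset({7, 8, 9})
WATER = frozenset({10, 11, 12, 13})
WETLAND = frozenset({17})
BUILT = frozenset({14, 15, 16})
BARREN = frozenset({18, 19})


def category_of(code: int) -> str:
    """Coarse category name for a LULC code."""
    if code in CROPLAND:
        return "cropland"
    if code in FOREST:
        return "forest"
    if code in GRASSLAND:
        return "grassland"
    if code in WATER:
        return "water"
    if code in WETLAND:
        return "wetland"
    if code in BUILT:
        return "built"
    if code in BARREN:
        return "barren"
    raise KeyError(f"unknown LULC code {code}")
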