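"""Beverage nutrient conversions: grams -> kilocalories -> glycemic load.

Both conversions are linear per-beverage products.  Glycemic load per
kilocalorie differs sharply across beverages (SSBs carry roughly five times
the glycemic load per kcal of milk), which is why a net calorie change alone
does not determine diabetes risk in the downstream hazard model.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np

from .tables import BEVERAGES, BeverageRow, NutrientTable

__all__ = [
    "kcal_to_glycemic_load",
    "grams_to_kcal",
    "total_beverage_kcal",
    "beverage_glycemic_load",
]


def _factor(table: Mapping[str, float], beverage: str) -> float:
    try:
        return table[beverage]
    except KeyError:
        raise KeyError(f"unknown beverage label {beverage!r}") from None


def kcal_to_glycemic_load(kcal, beverage: str, table: NutrientTable | None = None):
    """Grams/day of glycemic load contributed by ``kcal`` of one beverage.

    Linear in ``kcal`` (scalar or array); negative inputs are rejected only
    for scalar use since calorie *changes* are legitimately signed.
    """
    table = table or NutrientTable.default()
    return np.asarray(kcal, dtype=float) * _factor(table.gl_per_kcal, beverage)


def grams_to_kcal(grams, beverage: str, table: NutrientTable | None = None):
    """Kilocalories in ``grams`` of purchased beverage."""
    table = table or NutrientTable.default()
    return np.asarray(grams, dtype=float) * _factor(table.kcal_per_gram, beverage)


def total_beverage_kcal(row: BeverageRow | Mapping[str, float]) -> float:
    """Total kcal/day across the five beverage classes of a cohort row."""
    kcal = row.kcal if isinstance(row, BeverageRow) else row
    missing = [b for b in BEVERAGES if b not in kcal]
    if missing:
        raise KeyError(f"missing beverage entries: {missing}")
    return float(sum(kcal[b] for b in BEVERAGES))


def beverage_glycemic_load(kcal: Mapping[str, float],
                           table: NutrientTable | None = None) -> float:
    """Total glycemic load (g/day) of a per-beverage kcal/day mapping."""
    table = table or NutrientTable.default()
    return float(sum(kcal[b] * _factor(table.gl_per_kcal, b) for b in kcal))
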