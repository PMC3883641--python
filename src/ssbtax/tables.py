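"""Packaged parameter tables and their in-memory containers.

The package ships plain-text transcriptions of the study's input tables:
per-beverage price elasticities with respect to SSB price, per-cohort baseline
beverage energy intake / overweight prevalence / diabetes incidence, glycemic
load per kilocalorie, energy content per gram, and the metabolic parameters of
the two-compartment energy-balance model.  Loaders here return pandas frames
or small dataclasses; nothing downstream reads the CSV files directly.

Note on the cohort table: the source subgroup rows list the overweight and
incidence columns in transposed order (a value such as 156 cannot be a
percentage); the packaged file stores every value under the unit-consistent
column, so ``overweight_pct`` is always a percentage and
``diabetes_incidence`` always cases per 100,000 person-years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: The five beverage classes of the demand system, in canonical order.
BEVERAGES: tuple[str, ...] = ("milk", "ssb", "juice", "coffee", "tea")
#: Demand-system goods: the beverages plus the composite outside good.
GOODS: tuple[str, ...] = BEVERAGES + ("other",)

_DATA = resources.files("ssbtax") / "data"


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path)


def _read_json(name: str) -> dict:
    return json.loads((_DATA / name).read_text())


def load_elasticity_table() -> pd.DataFrame:
    """Per-segment beverage elasticities wrt a 1% SSB price change, with 95% CIs."""
    return _read_csv("elasticity_table1.csv")


def load_cohort_table() -> pd.DataFrame:
    """Baseline kcal/day per beverage, overweight %, and diabetes incidence by margin."""
    return _read_csv("cohort_table2.csv")


def load_generator_settings() -> dict:
    """Settings used to build the packaged household-generator ground truth."""
    return _read_json("generator_truth.json")


def elasticity_vector(segment: str = "overall", level: str = "overall") -> pd.Series:
    """Elasticity of each beverage wrt SSB price for one population segment.

    Returns a Series indexed by beverage, ordered as :data:`BEVERAGES`.
    """
    t = load_elasticity_table()
    sub = t[(t.segment == segment) & (t.level == level)]
    if sub.empty:
        raise KeyError(f"no elasticity row for segment={segment!r} level={level!r}")
    return sub.set_index("beverage")["elasticity"].reindex(list(BEVERAGES))


def elasticity_ci(segment: str = "overall", level: str = "overall") -> pd.DataFrame:
    t = load_elasticity_table()
    sub = t[(t.segment == segment) & (t.level == level)]
    return sub.set_index("beverage").reindex(list(BEVERAGES))[
        ["elasticity", "ci_low", "ci_high"]
    ]


@dataclass(frozen=True)
class NutrientTable:
    """Per-beverage nutrient conversion factors with 95% CIs.

    ``gl_per_kcal`` converts kilocalories to grams of glycemic load;
    ``kcal_per_gram`` converts purchased grams to kilocalories.
    """

    gl_per_kcal: dict[str, float]
    gl_ci: dict[str, tuple[float, float]]
    kcal_per_gram: dict[str, float]
    kcal_ci: dict[str, tuple[float, float]]

    def __post_init__(self):
        for name, table in (("gl_per_kcal", self.gl_per_kcal),
                            ("kcal_per_gram", self.kcal_per_gram)):
            if any(v <= 0 for v in table.values()):
                raise ValueError(f"{name} entries must be positive")

    @classmethod
    def default(cls) -> "NutrientTable":
        gl = _read_csv("glycemic_load_table3.csv").set_index("beverage")
        kc = _read_csv("kcal_per_gram.csv").set_index("beverage")
        return cls(
            gl_per_kcal=gl["gl_per_kcal"].to_dict(),
            gl_ci={b: (r.ci_low, r.ci_high) for b, r in gl.iterrows()},
            kcal_per_gram=kc["kcal_per_gram"].to_dict(),
            kcal_ci={b: (r.ci_low, r.ci_high) for b, r in kc.iterrows()},
        )


@dataclass(frozen=True)
class HallParameters:
    """Parameters of the two-compartment (fat/lean) energy-balance model.

    Energy densities are kcal per kg of tissue; ``gamma_fat``/``gamma_lean``
    are resting-metabolic-rate regression slopes on fat and lean mass;
    ``activity_coeff`` is physical-activity expenditure per kg body weight for
    a reference activity level (scaled by each individual's activity
    multiplier); ``tef_fraction`` is the thermic effect of food as a fraction
    of intake; ``at_beta``/``at_tau_days`` control adaptive thermogenesis;
    ``forbes_c`` is the Forbes lean-fat partitioning constant.
    """

    rho_fat: float = 9440.0
    rho_lean: float = 1807.0
    gamma_fat: float = 3.2
    gamma_lean: float = 22.0
    rmr_constant: float = 500.0
    activity_coeff: float = 9.0
    tef_fraction: float = 0.10
    at_beta: float = 0.14
    at_tau_days: float = 14.0
    forbes_c: float = 10.4
    include_adaptive_thermogenesis: bool = True

    def __post_init__(self):
        if self.rho_fat <= 0 or self.rho_lean <= 0:
            raise ValueError("energy densities must be positive")
        if self.rho_fat <= self.rho_lean:
            raise ValueError("fat must be more energy dense than lean tissue")

    @classmethod
    def default(cls, include_adaptive_thermogenesis: bool = True) -> "HallParameters":
        raw = _read_json("hall_parameters.json")
        return cls(
            rho_fat=raw["rho_fat"],
            rho_lean=raw["rho_lean"],
            gamma_fat=raw["gamma_fat"],
            gamma_lean=raw["gamma_lean"],
            rmr_constant=raw["rmr_constant"],
            activity_coeff=raw["activity_coeff"],
            tef_fraction=raw["tef_fraction"],
            at_beta=raw["at_beta"],
            at_tau_days=raw["at_tau_days"],
            forbes_c=raw["forbes_c"],
            include_adaptive_thermogenesis=include_adaptive_thermogenesis,
        )


@dataclass(frozen=True)
class HazardParameters:
    """Glycemic-load diabetes hazard: RR per +100 g/day GL, exponential
    effect rate (per year), and the rate's 95% CIs for uncertainty sampling."""

    relative_risk: float = 1.45
    rr_ci: tuple[float, float] = (1.31, 1.61)
    effect_rate: float = 1.0 / 7.6
    effect_rate_ci: tuple[float, float] = (1.0 / 14.7, 1.0 / 2.8)

    def __post_init__(self):
        if self.relative_risk <= 0:
            raise ValueError("relative risk must be positive")
        if self.effect_rate <= 0:
            raise ValueError("effect rate must be positive")


@dataclass(frozen=True)
class BeverageRow:
    """One cohort row of the baseline table: kcal/day per beverage plus
    overweight prevalence (fraction) and diabetes incidence (/100,000/yr)."""

    kcal: dict[str, float]
    kcal_sd: dict[str, float]
    overweight_prevalence: float
    overweight_sd: float
    diabetes_incidence: float
    diabetes_incidence_sd: float
    labels: dict[str, str] = field(default_factory=dict)


def cohort_row(segment: str = "overall", level: str = "overall") -> BeverageRow:
    t = load_cohort_table()
    sub = t[(t.segment == segment) & (t.level == level)]
    if sub.empty:
        raise KeyError(f"no cohort row for segment={segment!r} level={level!r}")
    r = sub.iloc[0]
    return BeverageRow(
        kcal={b: float(r[f"{b}_kcal"]) for b in BEVERAGES},
        kcal_sd={b: float(r[f"{b}_sd"]) for b in BEVERAGES},
        overweight_prevalence=float(r.overweight_pct) / 100.0,
        overweight_sd=float(r.overweight_sd) / 100.0,
        diabetes_incidence=float(r.diabetes_incidence),
        diabetes_incidence_sd=float(r.diabetes_incidence_sd),
        labels={"segment": segment, "level": level},
    )


def default_populations(total_adults: float = 550e6) -> dict[str, float]:
    """Illustrative population margin weights for absolute-case scaling.

    Census-style shares of the Indian adult (25-65) population; these stand in
    for official demographic projections, which are a user input.
    """
    return {
        "age:25-44": 0.62, "age:45-65": 0.38,
        "sex:male": 0.515, "sex:female": 0.485,
        "income:low": 0.28, "income:mid": 0.505, "income:high": 0.215,
        "residence:urban": 0.31, "residence:rural": 0.69,
        "total": total_adults,
    }
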