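"""Cohort microsimulation of tax scenarios with Monte-Carlo uncertainty.

The population is the cross of 2 age bands x 2 sexes x 3 income tertiles x
2 residence strata (24 cohorts).  Only margin-level baseline values are
available, so cell-level calibrations are filled by independent margin
effects (multiplicative for rates and intakes, additive on the log-odds
scale for prevalence) and then raked so the population-weighted cell means
reproduce the overall row exactly — a stated approximation, since the true
joint cell values are unobserved.

For each cohort a scenario run samples individuals, builds the consumption
path, feeds each individual's intake change through the energy-balance
model and their glycemic-load change through the diabetes hazard, and
aggregates yearly outcomes.  Paired scenario runs launched with the same
seed share every random draw (individuals and event uniforms), so scenario
contrasts are common-random-number paired.  Parameter uncertainty is
propagated by an outer Monte-Carlo loop that resamples every input
parameter from the normal distribution implied by its 95% CI (truncated
where a sign is constrained).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .diabetes import simulate_incidence
from .hall import initial_fat_mass, simulate_weight
from .scenarios import (BassFit, ConsumptionPath, bass_from_endpoints,
                        project_bass, project_linear, taxed_path)
from .synthetic.individuals import OVERWEIGHT_BMI, generate_individuals
from .tables import (BEVERAGES, BeverageRow, HallParameters, HazardParameters,
                     NutrientTable, cohort_row, default_populations,
                     elasticity_ci)

__all__ = ["CohortSpec", "ParameterBundle", "build_cohorts", "run_scenario",
           "run_paired", "overall_outcomes", "relative_reduction",
           "uncertainty_run", "cases_averted"]

AGE_BANDS = ("25-44", "45-65")
SEXES = ("male", "female")
INCOMES = ("low", "mid", "high")
RESIDENCES = ("urban", "rural")

_AGE_MID = {"25-44": 35.0, "45-65": 55.0}


@dataclass
class CohortSpec:
    """One simulation cell: labels, size, population weight and calibration."""

    labels: dict[str, str]
    n: int
    weight: float
    row: BeverageRow
    elasticity: pd.Series
    elasticity_ci: pd.DataFrame
    population: float | None = None

    @property
    def key(self) -> str:
        return "|".join(self.labels[k] for k in ("age", "sex", "income",
                                                 "residence"))


def _margin_weights(populations: dict[str, float]) -> dict[tuple[str, str], float]:
    return {(seg, lvl): populations[f"{seg}:{lvl}"]
            for seg, levels in (("age", AGE_BANDS), ("sex", SEXES),
                                ("income", INCOMES), ("residence", RESIDENCES))
            for lvl in levels}


def build_cohorts(n_individuals: int = 2000,
                  populations: dict[str, float] | None = None) -> list[CohortSpec]:
    """The full 24-cell design with raked cell-level calibrations."""
    populations = populations or default_populations()
    mw = _margin_weights(populations)
    margin_rows = {(seg, lvl): cohort_row(seg if seg != "age" else "age", lvl)
                   for (seg, lvl) in mw}
    # margin segment names in the packaged table
    overall = cohort_row("overall", "overall")

    cells = [dict(age=a, sex=s, income=i, residence=r)
             for a in AGE_BANDS for s in SEXES for i in INCOMES
             for r in RESIDENCES]
    weights = np.array([mw[("age", c["age"])] * mw[("sex", c["sex"])]
                        * mw[("income", c["income"])]
                        * mw[("residence", c["residence"])] for c in cells])
    weights = weights / weights.sum()

    def margin_list(c):
        return [("age", c["age"]), ("sex", c["sex"]), ("income", c["income"]),
                ("residence", c["residence"])]

    # kcal and incidence: independent multiplicative margin effects, rescaled
    kcal_cells = {b: np.array([
        overall.kcal[b] * np.prod([margin_rows[m].kcal[b] / overall.kcal[b]
                                   for m in margin_list(c)])
        for c in cells]) for b in BEVERAGES}
    for b in BEVERAGES:
        kcal_cells[b] *= overall.kcal[b] / (weights * kcal_cells[b]).sum()

    inc_cells = np.array([
        overall.diabetes_incidence
        * np.prod([margin_rows[m].diabetes_incidence
                   / overall.diabetes_incidence for m in margin_list(c)])
        for c in cells])
    inc_cells *= overall.diabetes_incidence / (weights * inc_cells).sum()

    # prevalence: additive margin effects on the log-odds scale, then a
    # common offset so the weighted mean matches the overall prevalence
    l0 = logit(overall.overweight_prevalence)
    lo = np.array([
        l0 + sum(logit(margin_rows[m].overweight_prevalence) - l0
                 for m in margin_list(c)) for c in cells])
    off = brentq(lambda d: (weights * expit(lo + d)).sum()
                 - overall.overweight_prevalence, -5, 5)
    prev_cells = expit(lo + off)

    def rel_sd(values):
        return max(values)

    cohorts = []
    for j, c in enumerate(cells):
        rels_prev = rel_sd([margin_rows[m].overweight_sd
                            / margin_rows[m].overweight_prevalence
                            for m in margin_list(c)])
        rels_inc = rel_sd([margin_rows[m].diabetes_incidence_sd
                           / margin_rows[m].diabetes_incidence
                           for m in margin_list(c)])
        row = BeverageRow(
            kcal={b: float(kcal_cells[b][j]) for b in BEVERAGES},
            kcal_sd={b: float(kcal_cells[b][j] * overall.kcal_sd[b]
                              / overall.kcal[b]) for b in BEVERAGES},
            overweight_prevalence=float(prev_cells[j]),
            overweight_sd=float(prev_cells[j] * rels_prev),
            diabetes_incidence=float(inc_cells[j]),
            diabetes_incidence_sd=float(inc_cells[j] * rels_inc),
            labels=dict(c),
        )
        e_inc = elasticity_ci("income", c["income"])
        e_res = elasticity_ci("residence", c["residence"])
        eci = (e_inc + e_res) / 2.0
        cohorts.append(CohortSpec(
            labels=dict(c), n=n_individuals, weight=float(weights[j]),
            row=row, elasticity=eci["elasticity"],
            elasticity_ci=eci[["ci_low", "ci_high"]]))
    return cohorts


@dataclass
class ParameterBundle:
    """Central parameter values plus the machinery to resample them."""

    nutrients: NutrientTable = field(default_factory=NutrientTable.default)
    hall: HallParameters = field(default_factory=HallParameters.default)
    hazard: HazardParameters = field(default_factory=HazardParameters)

    @staticmethod
    def _ci_normal(rng, point, lo, hi, floor=None):
        sd = (hi - lo) / 3.92
        for _ in range(100):
            v = rng.normal(point, sd)
            if floor is None or v > floor:
                return float(v)
        return float(point)

    def sample(self, rng: np.random.Generator,
               cohorts: list[CohortSpec]) -> tuple["ParameterBundle",
                                                   list[CohortSpec]]:
        """One outer Monte-Carlo draw of every uncertain input parameter."""
        gl = {b: self._ci_normal(rng, self.nutrients.gl_per_kcal[b],
                                 *self.nutrients.gl_ci[b], floor=0.0)
              for b in BEVERAGES}
        nutrients = dataclasses.replace(self.nutrients, gl_per_kcal=gl)
        rel = 0.05
        hall = dataclasses.replace(
            self.hall,
            gamma_fat=self.hall.gamma_fat * max(rng.normal(1.0, rel), 0.5),
            gamma_lean=self.hall.gamma_lean * max(rng.normal(1.0, rel), 0.5),
            activity_coeff=self.hall.activity_coeff
            * max(rng.normal(1.0, rel), 0.5),
            forbes_c=self.hall.forbes_c * max(rng.normal(1.0, rel), 0.5),
        )
        hazard = HazardParameters(
            relative_risk=self._ci_normal(rng, self.hazard.relative_risk,
                                          *self.hazard.rr_ci, floor=1.0),
            effect_rate=self._ci_normal(rng, self.hazard.effect_rate,
                                        *self.hazard.effect_rate_ci,
                                        floor=0.01),
        )
        new_cohorts = []
        for c in cohorts:
            kcal = {b: max(rng.normal(c.row.kcal[b], c.row.kcal_sd[b]), 0.1)
                    for b in BEVERAGES}
            prev = float(np.clip(rng.normal(c.row.overweight_prevalence,
                                            c.row.overweight_sd),
                                 0.005, 0.98))
            inc = max(rng.normal(c.row.diabetes_incidence,
                                 c.row.diabetes_incidence_sd), 1.0)
            row = dataclasses.replace(c.row, kcal=kcal,
                                      overweight_prevalence=prev,
                                      diabetes_incidence=inc)
            e = pd.Series({b: self._ci_normal(
                rng, c.elasticity[b], c.elasticity_ci.loc[b, "ci_low"],
                c.elasticity_ci.loc[b, "ci_high"]) for b in BEVERAGES})
            new_cohorts.append(replace(c, row=row, elasticity=e))
        return (ParameterBundle(nutrients=nutrients, hall=hall,
                                hazard=hazard), new_cohorts)


def _cohort_path(cohort: CohortSpec, *, trend: str, growth: float,
                 growth_kind: str, years, bass: BassFit | None) -> ConsumptionPath:
    if trend == "linear":
        return project_linear(cohort.row, growth=growth, years=years,
                              kind=growth_kind)
    if trend == "bass":
        return project_bass(cohort.row, bass=bass, years=years)
    raise ValueError(f"unknown trend {trend!r}")


def run_scenario(cohorts: list[CohortSpec],
                 bundle: ParameterBundle | None = None,
                 *,
                 tax_rate: float | None = None,
                 trend: str = "linear",
                 growth: float = 0.13,
                 growth_kind: str = "increment",
                 years=range(2014, 2024),
                 nonbev_kcal_per_year: float = 12.0,
                 bass: BassFit | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """One full scenario run at fixed parameters (a single inner draw).

    Runs launched with the same ``seed`` and cohort list share every random
    number, so a baseline/taxed pair is a common-random-number contrast:
    a zero tax reproduces the baseline run exactly.
    """
    bundle = bundle or ParameterBundle()
    years = np.asarray(list(years))
    n_years = len(years)
    if trend == "bass" and bass is None:
        bass = bass_from_endpoints(year_start=int(years[0]),
                                   year_end=int(years[-1]))
    gl_fac = np.array([bundle.nutrients.gl_per_kcal[b] for b in BEVERAGES])

    records = []
    for ci, cohort in enumerate(cohorts):
        ss = np.random.SeedSequence([int(seed), ci])
        s_ind, s_unif = ss.spawn(2)
        ind = generate_individuals(cohort.n,
                                   {"age": cohort.labels["age"],
                                    "sex": cohort.labels["sex"],
                                    "income": cohort.labels["income"],
                                    "residence": cohort.labels["residence"]},
                                   cohort.row, seed=s_ind)
        uniforms = np.random.default_rng(s_unif).random((cohort.n, n_years))

        base = _cohort_path(cohort, trend=trend, growth=growth,
                            growth_kind=growth_kind, years=years, bass=bass)
        path = base if tax_rate is None else taxed_path(
            base, cohort.elasticity, tax_rate)
        ratios = path.kcal.to_numpy() / base.kcal.iloc[0].to_numpy()[None, :]

        kcal0 = ind[[f"kcal_{b}" for b in BEVERAGES]].to_numpy()
        dk = kcal0 @ (ratios - 1.0).T          # (n, n_years) beverage change
        nonbev = nonbev_kcal_per_year * np.arange(n_years)
        delta_intake = dk + nonbev[None, :]
        dgl = (kcal0 * gl_fac[None, :]) @ (ratios - 1.0).T

        fat0 = initial_fat_mass(ind.weight.to_numpy(), ind.height.to_numpy(),
                                _AGE_MID[cohort.labels["age"]],
                                ind.sex.to_numpy())
        traj = simulate_weight(ind.weight.to_numpy(), fat0, delta_intake,
                               ind.activity.to_numpy(), bundle.hall)
        bmi = traj.weight[:, 1:] / ind.height.to_numpy()[:, None] ** 2

        res = simulate_incidence(ind.diabetes.to_numpy(), dgl,
                                 cohort.row.diabetes_incidence,
                                 bundle.hazard, years=years,
                                 uniforms=uniforms)
        mean_kcal = kcal0.mean(axis=0) @ ratios.T
        for k, year in enumerate(years):
            records.append({
                **cohort.labels, "cohort": cohort.key,
                "weight": cohort.weight, "year": int(year),
                "overweight_prevalence": float((bmi[:, k] >= OVERWEIGHT_BMI).mean()),
                "diabetes_incidence": float(res.expected_incidence[k]),
                "diabetes_incidence_observed": float(res.observed_incidence[k]),
                "at_risk": int(res.at_risk[k]),
                "mean_beverage_kcal": float(mean_kcal[k]),
                "mean_delta_gl": float(dgl[:, k].mean()),
            })
    df = pd.DataFrame.from_records(records)
    df.attrs["scenario"] = {"tax_rate": tax_rate, "trend": trend,
                            "growth": growth, "growth_kind": growth_kind,
                            "seed": seed}
    return df


def run_paired(cohorts, bundle=None, *, tax_rate: float, seed: int = 0,
               **scenario_kw) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline and taxed runs with common random numbers."""
    base = run_scenario(cohorts, bundle, tax_rate=None, seed=seed,
                        **scenario_kw)
    taxed = run_scenario(cohorts, bundle, tax_rate=tax_rate, seed=seed,
                         **scenario_kw)
    return base, taxed


def overall_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    """Population-weighted yearly outcomes across cohorts."""
    def agg(g):
        w = g["weight"] / g["weight"].sum()
        return pd.Series({
            "overweight_prevalence": float((w * g.overweight_prevalence).sum()),
            "diabetes_incidence": float((w * g.diabetes_incidence).sum()),
            "mean_beverage_kcal": float((w * g.mean_beverage_kcal).sum()),
        })
    return df.groupby("year").apply(agg, include_groups=False)


def relative_reduction(base: pd.DataFrame, taxed: pd.DataFrame,
                       measure: str = "overweight_prevalence",
                       year: int | None = None) -> float:
    """Percent reduction of a population-level outcome vs baseline.

    Defaults to the final simulated year.
    """
    ob, ot = overall_outcomes(base), overall_outcomes(taxed)
    if year is None:
        year = int(ob.index.max())
    b, t = ob.loc[year, measure], ot.loc[year, measure]
    if b == 0:
        raise ZeroDivisionError("baseline outcome is zero")
    return float((b - t) / b * 100.0)


def margin_outcomes(df: pd.DataFrame, segment: str) -> pd.DataFrame:
    """Population-weighted yearly outcomes aggregated to one margin
    (``age``, ``sex``, ``income`` or ``residence``)."""
    def agg(g):
        w = g["weight"] / g["weight"].sum()
        return pd.Series({
            "overweight_prevalence": float((w * g.overweight_prevalence).sum()),
            "diabetes_incidence": float((w * g.diabetes_incidence).sum()),
        })
    return df.groupby([segment, "year"]).apply(agg, include_groups=False)


def margin_reductions(base: pd.DataFrame, taxed: pd.DataFrame,
                      measure: str = "overweight_prevalence",
                      year: int | None = None) -> pd.Series:
    """Relative reduction (%) of an outcome per margin level, as the
    subgroup results are reported."""
    out = {}
    if year is None:
        year = int(base.year.max())
    for segment in ("age", "sex", "income", "residence"):
        ob = margin_outcomes(base, segment)
        ot = margin_outcomes(taxed, segment)
        for level in ob.index.get_level_values(0).unique():
            b = ob.loc[(level, year), measure]
            t = ot.loc[(level, year), measure]
            out[f"{segment}:{level}"] = float((b - t) / b * 100.0)
    return pd.Series(out)


def uncertainty_run(cohorts, bundle=None, *, tax_rate: float = 0.20,
                    n_outer: int = 200, seed: int = 0,
                    sample_parameters: bool = True,
                    reseed_draws: bool = True,
                    **scenario_kw) -> dict:
    """Outer Monte-Carlo loop over parameter draws of paired runs.

    Returns per-draw overall contrasts and percentile (2.5/97.5) intervals.
    ``sample_parameters=False`` with ``reseed_draws=False`` collapses every
    draw onto the central run (useful for degeneracy checks).
    """
    if n_outer < 2:
        raise ValueError("n_outer must be >= 2")
    bundle = bundle or ParameterBundle()
    prng = np.random.default_rng(np.random.SeedSequence([int(seed), 424242]))
    rows = []
    for d in range(n_outer):
        if sample_parameters:
            b_d, c_d = bundle.sample(prng, cohorts)
        else:
            b_d, c_d = bundle, cohorts
        inner = seed + d + 1 if reseed_draws else seed
        base, taxed = run_paired(c_d, b_d, tax_rate=tax_rate, seed=inner,
                                 **scenario_kw)
        ob = overall_outcomes(base)
        last = int(ob.index.max())
        rows.append({
            "draw": d,
            "overweight_reduction_pct": relative_reduction(
                base, taxed, "overweight_prevalence"),
            "diabetes_reduction_pct": relative_reduction(
                base, taxed, "diabetes_incidence"),
            "baseline_overweight_final": float(
                ob.loc[last, "overweight_prevalence"]),
            "baseline_incidence_final": float(
                ob.loc[last, "diabetes_incidence"]),
        })
    draws = pd.DataFrame(rows)
    summary = draws.drop(columns="draw").agg(
        ["mean", lambda s: s.quantile(0.025), lambda s: s.quantile(0.975)])
    summary.index = ["mean", "ci_low", "ci_high"]
    return {"draws": draws, "summary": summary,
            "config": {"tax_rate": tax_rate, "n_outer": n_outer,
                       "seed": seed, **scenario_kw}}


def cases_averted(base: pd.DataFrame, taxed: pd.DataFrame,
                  populations: dict[str, float]) -> dict:
    """Absolute cases averted, scaled by per-cohort population counts.

    Overweight is accumulated as prevalence differences summed over the
    horizon (person-years of overweight averted); diabetes as the cumulative
    incidence difference.  ``populations`` maps cohort keys to head counts.
    """
    merged = base.merge(taxed, on=["cohort", "year"],
                        suffixes=("_base", "_tax"))
    out_rows = []
    for cohort, g in merged.groupby("cohort"):
        if cohort not in populations:
            raise KeyError(f"missing population for cohort {cohort}")
        pop = populations[cohort]
        ow = float((g.overweight_prevalence_base
                    - g.overweight_prevalence_tax).sum() * pop)
        dm = float(((g.diabetes_incidence_base
                     - g.diabetes_incidence_tax) / 1e5).sum() * pop)
        out_rows.append({"cohort": cohort, "population": pop,
                         "overweight_averted": ow, "diabetes_averted": dm})
    per = pd.DataFrame(out_rows)
    return {"overweight_averted": float(per.overweight_averted.sum()),
            "diabetes_averted": float(per.diabetes_averted.sum()),
            "by_cohort": per}


def cohort_populations(cohorts: list[CohortSpec],
                       total: float = 550e6) -> dict[str, float]:
    """Population counts per cohort from the design weights."""
    return {c.key: c.weight * total for c in cohorts}
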