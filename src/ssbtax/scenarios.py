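"""Consumption scenarios: secular trends, Bass diffusion, and tax shocks.

The counterfactual machinery works on per-cohort, per-year, per-beverage
kcal/day paths.  Baselines either grow the SSB component linearly (constant
annual increment equal to a fraction of the first-year level, with a
compound-growth switch) or along a Bass diffusion curve; non-SSB beverages
are held flat, matching the absence of significant secular trends in their
consumption.  A tax of rate ``tau`` perturbs each year of the baseline path
through the elasticity column wrt SSB price:

    delta_kcal_b(t) = e_{b,SSB} * (100 * tau) * kcal_b(t) / 100

with consumption floored at zero.  Elasticities are treated as constant over
the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .tables import BEVERAGES, BeverageRow, NutrientTable

__all__ = ["ConsumptionPath", "apply_tax_shock", "project_linear",
           "project_bass", "fit_bass", "BassFit", "bass_from_endpoints",
           "taxed_path", "path_glycemic_load"]


@dataclass
class ConsumptionPath:
    """Per-year, per-beverage kcal/day for one cohort under one scenario."""

    kcal: pd.DataFrame            # index: years, columns: beverages
    scenario: str = "baseline"
    meta: dict = field(default_factory=dict)

    @property
    def years(self) -> np.ndarray:
        return self.kcal.index.to_numpy()

    def ratios(self) -> pd.DataFrame:
        """Each year's kcal relative to the first (anchor) year."""
        anchor = self.kcal.iloc[0]
        out = self.kcal / anchor.replace(0.0, np.nan)
        return out.fillna(1.0)

    def total(self) -> pd.Series:
        return self.kcal.sum(axis=1)


def apply_tax_shock(elasticity: pd.Series, tau: float,
                    baseline_kcal: pd.Series) -> pd.Series:
    """Per-beverage kcal/day change from an SSB price rise of ``100*tau`` %.

    Floored so that post-shock consumption cannot go negative.
    """
    if tau < 0:
        raise ValueError("tax rate must be >= 0")
    missing = [b for b in baseline_kcal.index if b not in elasticity.index
               or pd.isna(elasticity[b])]
    if missing:
        raise KeyError(f"missing elasticity entries: {missing}")
    base = baseline_kcal.astype(float)
    if (base < 0).any():
        raise ValueError("baseline kcal must be >= 0")
    delta = elasticity.loc[base.index] * (100.0 * tau) * base / 100.0
    return delta.clip(lower=-base)


def project_linear(baseline: BeverageRow, growth: float = 0.13,
                   years=range(2014, 2024),
                   kind: str = "increment") -> ConsumptionPath:
    """Baseline path with an SSB secular trend and flat non-SSB beverages.

    ``kind='increment'`` adds a constant ``growth`` fraction of the anchor
    level each year (the default reading of a "13% per annum" rise fitted to
    a near-linear historical series); ``kind='compound'`` compounds
    year-on-year.
    """
    if growth < 0:
        raise ValueError("growth must be >= 0")
    years = np.asarray(list(years))
    k = np.arange(len(years), dtype=float)
    if kind == "increment":
        ssb_mult = 1.0 + growth * k
    elif kind == "compound":
        ssb_mult = (1.0 + growth) ** k
    else:
        raise ValueError(f"unknown growth kind {kind!r}")
    df = pd.DataFrame({b: np.full(len(years), baseline.kcal[b])
                       for b in BEVERAGES}, index=years)
    df["ssb"] = baseline.kcal["ssb"] * ssb_mult
    return ConsumptionPath(kcal=df, scenario=f"baseline-linear-{kind}",
                           meta={"growth": growth, "kind": kind})


def _bass_cumulative(t: np.ndarray, m: float, p: float, q: float) -> np.ndarray:
    """Bass adoption level m*F(t) with innovation p and imitation q."""
    t = np.asarray(t, dtype=float)
    e = np.exp(-(p + q) * t)
    return m * (1.0 - e) / (1.0 + (q / p) * e)


@dataclass
class BassFit:
    m: float
    p: float
    q: float
    r2: float
    t0: float = 0.0

    def __call__(self, years) -> np.ndarray:
        return _bass_cumulative(np.asarray(years, dtype=float) - self.t0,
                                self.m, self.p, self.q)


def fit_bass(years, series, t0: float | None = None) -> BassFit:
    """Least-squares Bass fit to an annual consumption series.

    ``t0`` anchors the diffusion clock (defaults to one year before the first
    observation).  Raises on non-convergence.
    """
    years = np.asarray(years, dtype=float)
    series = np.asarray(series, dtype=float)
    if len(years) < 4:
        raise ValueError("need at least 4 observations")
    if series[-1] <= series[0]:
        raise ValueError("series must be increasing overall")
    if t0 is None:
        t0 = years[0] - 1.0
    t = years - t0
    m0 = 3.0 * series.max()
    try:
        popt, _ = curve_fit(_bass_cumulative, t, series,
                            p0=[m0, 0.01, 0.3],
                            bounds=([1e-9, 1e-9, 0.0], [1e6, 5.0, 5.0]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Bass fit did not converge: {exc}") from exc
    pred = _bass_cumulative(t, *popt)
    ss_res = float(np.sum((series - pred) ** 2))
    ss_tot = float(np.sum((series - series.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BassFit(m=float(popt[0]), p=float(popt[1]), q=float(popt[2]),
                   r2=r2, t0=t0)


def bass_from_endpoints(v_start: float = 12.8, v_end: float = 36.3,
                        year_start: int = 2014, year_end: int = 2023,
                        anchor: tuple[float, float] = (2012.0, 11.0),
                        t0: float = 1998.0) -> BassFit:
    """Bass curve through the two projection endpoints, as close as
    possible to the historical anchor.

    The two endpoints are interpolated exactly.  A cumulative diffusion
    curve has a monotonically declining relative growth rate, so it cannot
    also pass exactly through an anchor observation implying slower growth
    before the start year than after it; the remaining degree of freedom
    (the imitation/innovation ratio) is therefore spent minimising the
    anchor residual.
    """
    ratio = v_end / v_start
    t1, t2 = float(year_start) - t0, float(year_end) - t0
    ta = anchor[0] - t0

    def g(t, s, r):
        e = np.exp(-s * t)
        return (1.0 - e) / (1.0 + r * e)

    def solve_s(r):
        # ratio(s) runs from t2/t1 (s->0) through a peak back to 1 (s->inf)
        f = lambda s: g(t2, s, r) / g(t1, s, r) - ratio
        grid = np.geomspace(1e-3, 3.0, 200)
        vals = np.array([f(s) for s in grid])
        sign = np.sign(vals)
        idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
        if len(idx) == 0:
            return None
        from scipy.optimize import brentq as _brentq
        return _brentq(f, grid[idx[0]], grid[idx[0] + 1], xtol=1e-14)

    def anchor_err(logr):
        r = np.exp(logr)
        s = solve_s(r)
        if s is None:
            return 1e6
        m = v_start / g(t1, s, r)
        return (m * g(ta, s, r) - anchor[1]) ** 2

    from scipy.optimize import minimize_scalar
    sol = minimize_scalar(anchor_err, bounds=(np.log(1e-3), np.log(1e5)),
                          method="bounded",
                          options={"xatol": 1e-10})
    r = float(np.exp(sol.x))
    s = solve_s(r)
    if s is None:
        raise RuntimeError("endpoint calibration failed: no feasible curve")
    m = v_start / g(t1, s, r)
    p = s / (1.0 + r)
    q = s - p
    fit = BassFit(m=float(m), p=float(p), q=float(q), r2=1.0, t0=t0)
    check = fit([year_start, year_end])
    if not np.allclose(check, [v_start, v_end], rtol=1e-9):
        raise RuntimeError("endpoint calibration failed to interpolate")
    return fit


def project_bass(baseline: BeverageRow, bass: BassFit | None = None,
                 years=range(2014, 2024)) -> ConsumptionPath:
    """Baseline path whose SSB component follows a Bass diffusion curve,
    rescaled so the anchor year matches the cohort's baseline SSB kcal."""
    bass = bass or bass_from_endpoints()
    years = np.asarray(list(years))
    level = bass(years)
    mult = level / level[0]
    df = pd.DataFrame({b: np.full(len(years), baseline.kcal[b])
                       for b in BEVERAGES}, index=years)
    df["ssb"] = baseline.kcal["ssb"] * mult
    return ConsumptionPath(kcal=df, scenario="baseline-bass",
                           meta={"bass": bass})


def taxed_path(baseline: ConsumptionPath, elasticity: pd.Series,
               tau: float, start_year: int | None = None) -> ConsumptionPath:
    """Apply the tax shock to every year of the baseline path from
    ``start_year`` (default: the first year) onward."""
    if start_year is None:
        start_year = int(baseline.kcal.index[0])
    out = baseline.kcal.copy()
    for year in out.index:
        if year >= start_year:
            row = out.loc[year]
            out.loc[year] = row + apply_tax_shock(elasticity, tau, row)
    return ConsumptionPath(kcal=out, scenario=f"tax-{tau:g}",
                           meta={**baseline.meta, "tau": tau,
                                 "baseline": baseline.scenario})


def path_glycemic_load(path: ConsumptionPath,
                       table: NutrientTable | None = None) -> pd.Series:
    """Total beverage glycemic load (g/day) per year of a path."""
    table = table or NutrientTable.default()
    factors = pd.Series({b: table.gl_per_kcal[b] for b in path.kcal.columns})
    return (path.kcal * factors).sum(axis=1)
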