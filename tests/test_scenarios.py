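"""Tax shocks, trend projections and Bass diffusion fitting."""

import numpy as np
import pandas as pd
import pytest

from ssbtax.nutrients import kcal_to_glycemic_load
from ssbtax.scenarios import (BassFit, _bass_cumulative, apply_tax_shock,
                              bass_from_endpoints, fit_bass,
                              path_glycemic_load, project_bass,
                              project_linear, taxed_path)
from ssbtax.tables import NutrientTable, cohort_row, elasticity_vector


@pytest.fixture(scope="module")
def overall():
    return cohort_row("overall", "overall")


@pytest.fixture(scope="module")
def e_vec():
    return elasticity_vector("overall", "overall")


def test_zero_tax_is_null(overall, e_vec):
    delta = apply_tax_shock(e_vec, 0.0, pd.Series(overall.kcal))
    assert (delta == 0).all()


def test_tax_shock_hand_products(overall, e_vec):
    """Hand product of the elasticity column and the baseline intakes:
    SSB -0.94 * 20 * 46 / 100 = -8.65 kcal/day, net ~ -2.4."""
    delta = apply_tax_shock(e_vec, 0.20, pd.Series(overall.kcal))
    assert delta["ssb"] == pytest.approx(-8.648, abs=1e-3)
    assert delta["milk"] == pytest.approx(2.029, abs=1e-3)
    assert delta["juice"] == pytest.approx(2.108, abs=1e-3)
    assert delta["tea"] == pytest.approx(2.132, abs=1e-3)
    assert delta.sum() == pytest.approx(-2.36, abs=0.05)


def test_tax_shock_glycemic_load(overall, e_vec):
    """Net glycemic-load change of the 20% shock is ~ -1.0 g/day."""
    table = NutrientTable.default()
    delta = apply_tax_shock(e_vec, 0.20, pd.Series(overall.kcal))
    gl = sum(float(kcal_to_glycemic_load(delta[b], b, table))
             for b in delta.index)
    assert gl == pytest.approx(-1.0, abs=0.05)


def test_tax_shock_floor():
    e = pd.Series({"ssb": -3.0})
    base = pd.Series({"ssb": 10.0})
    delta = apply_tax_shock(e, 0.5, base)
    assert delta["ssb"] == -10.0  # floored at zero consumption


def test_missing_elasticity_rejected(overall):
    with pytest.raises(KeyError):
        apply_tax_shock(pd.Series({"ssb": -0.94}), 0.2,
                        pd.Series(overall.kcal))


def test_linear_projection_oracles(overall):
    """Arithmetic and geometric series oracles for the SSB trend."""
    flat = project_linear(overall, growth=0.0)
    assert (flat.kcal.nunique() == 1).all()
    inc = project_linear(overall, growth=0.13, kind="increment")
    assert inc.kcal.loc[2023, "ssb"] == pytest.approx(46 * (1 + 0.13 * 9))
    comp = project_linear(overall, growth=0.13, kind="compound")
    assert comp.kcal.loc[2023, "ssb"] == pytest.approx(46 * 1.13 ** 9)
    # non-SSB beverages held flat
    assert (inc.kcal["milk"] == overall.kcal["milk"]).all()


def test_bass_self_consistency():
    """Noise-free series from known (m, p, q) is recovered with R^2 = 1."""
    years = np.arange(2000, 2014)
    true = BassFit(m=50.0, p=0.02, q=0.4, r2=1.0, t0=1999.0)
    fit = fit_bass(years, true(years), t0=1999.0)
    assert fit.m == pytest.approx(true.m, rel=1e-3)
    assert fit.p == pytest.approx(true.p, rel=1e-3)
    assert fit.q == pytest.approx(true.q, rel=1e-3)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)


def test_bass_pure_innovation_limit():
    """q = 0 truth (exponential-saturation adoption) yields q-hat ~ 0."""
    years = np.arange(2000, 2012)
    t = years - 1999.0
    series = 30.0 * (1.0 - np.exp(-0.15 * t))
    fit = fit_bass(years, series, t0=1999.0)
    assert fit.q == pytest.approx(0.0, abs=1e-4)
    assert fit.m == pytest.approx(30.0, rel=1e-3)


def test_bass_requires_enough_points():
    with pytest.raises(ValueError):
        fit_bass([2000, 2001, 2002], [1, 2, 3])


def test_bass_endpoint_calibration():
    """The calibrated diffusion path interpolates both printed endpoints."""
    bf = bass_from_endpoints()
    v = bf([2014, 2023])
    assert v[0] == pytest.approx(12.8, rel=1e-9)
    assert v[1] == pytest.approx(36.3, rel=1e-9)


def test_taxed_path_null_and_ordering(overall, e_vec):
    base = project_linear(overall)
    t0 = taxed_path(base, e_vec, 0.0)
    pd.testing.assert_frame_equal(t0.kcal, base.kcal)
    t20 = taxed_path(base, e_vec, 0.20)
    assert (t20.kcal["ssb"] < base.kcal["ssb"]).all()
    # substitution signs: milk, juice, tea rise; coffee essentially flat
    for b in ("milk", "juice", "tea"):
        assert (t20.kcal[b] > base.kcal[b]).all()
    assert np.allclose(t20.kcal["coffee"], base.kcal["coffee"], rtol=0.01)


@pytest.mark.parametrize("measure", ["ssb", "total"])
def test_tax_monotonicity(overall, e_vec, measure):
    """Higher tax, weakly lower SSB (and total) consumption each year."""
    base = project_linear(overall)
    prev = base.kcal["ssb"] if measure == "ssb" else base.total()
    for tau in (0.1, 0.2, 0.3):
        t = taxed_path(base, e_vec, tau)
        cur = t.kcal["ssb"] if measure == "ssb" else t.total()
        assert (cur <= prev + 1e-12).all()
        prev = cur


def test_bass_exceeds_linear_late(overall):
    """The endpoint-calibrated diffusion path overtakes the arithmetic
    trend by the end of the horizon (the amplification mechanism)."""
    lin = project_linear(overall)
    bas = project_bass(overall)
    assert bas.kcal.loc[2023, "ssb"] > lin.kcal.loc[2023, "ssb"]
    assert bas.kcal.loc[2014, "ssb"] == pytest.approx(
        lin.kcal.loc[2014, "ssb"])


def test_path_glycemic_load_linearity(overall):
    base = project_linear(overall)
    gl = path_glycemic_load(base)
    table = NutrientTable.default()
    hand = sum(base.kcal.loc[2014, b] * table.gl_per_kcal[b]
               for b in base.kcal.columns)
    assert gl.loc[2014] == pytest.approx(hand)
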