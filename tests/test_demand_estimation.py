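"""Two-step censored QUAIDS estimation: recovery and limiting cases."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ssbtax.demand.censoring import DegenerateCensoringError, fit_first_stage
from ssbtax.demand.estimate import fit_quaids, two_step_fit
from ssbtax.demand.quaids import DemandParameters
from ssbtax.synthetic import generate_households
from ssbtax.tables import BEVERAGES, GOODS


def test_noise_free_recovery(clean_truth, p_ref):
    """Exact data from a known parameter set is recovered to <= 1e-4."""
    df = generate_households(5000, clean_truth, seed=3)
    fit = fit_quaids(df, None, alpha0=clean_truth.params.alpha0, p_ref=p_ref)
    assert fit.converged
    for name in ("alpha", "beta", "lam", "gamma"):
        got = getattr(fit.params, name)
        want = getattr(clean_truth.params, name)
        np.testing.assert_allclose(got, want, atol=1e-4)


def test_homothetic_degenerate_fit(clean_truth, p_ref):
    """Constant-share data yields gamma-hat, beta-hat, lambda-hat ~ 0."""
    G = len(GOODS)
    params = DemandParameters(
        alpha=clean_truth.params.alpha.copy(), beta=np.zeros(G),
        lam=np.zeros(G), gamma=np.zeros((G, G)),
        alpha0=clean_truth.params.alpha0)
    hom = dataclasses.replace(clean_truth, params=params)
    df = generate_households(4000, hom, seed=5)
    fit = fit_quaids(df, None, alpha0=params.alpha0, p_ref=p_ref)
    np.testing.assert_allclose(fit.params.gamma, 0.0, atol=1e-8)
    np.testing.assert_allclose(fit.params.beta, 0.0, atol=1e-8)
    np.testing.assert_allclose(fit.params.lam, 0.0, atol=1e-8)
    np.testing.assert_allclose(fit.params.alpha, params.alpha, atol=1e-8)


def test_dropped_equation_invariance(clean_truth, p_ref):
    """With the constraints imposed, the fitted system does not depend on
    which share equation is excluded (exact on noise-free data)."""
    df = generate_households(3000, clean_truth, seed=7)
    f1 = fit_quaids(df, None, drop="other", alpha0=clean_truth.params.alpha0,
                    p_ref=p_ref)
    f2 = fit_quaids(df, None, drop="tea", alpha0=clean_truth.params.alpha0,
                    p_ref=p_ref)
    np.testing.assert_allclose(f1.params.gamma, f2.params.gamma, atol=1e-7)
    np.testing.assert_allclose(f1.params.alpha, f2.params.alpha, atol=1e-7)


def test_first_stage_no_censoring_limit(households_10k):
    """A beverage everyone consumes gets Phi = 1, phi = 0, and the corrected
    fit coincides with the uncensored one when nothing is censored."""
    df = households_10k.copy()
    df["qty_milk"] = np.maximum(df["qty_milk"], 1e-6)
    fs = fit_first_stage(df, "milk")
    assert not fs.censored
    np.testing.assert_array_equal(fs.cdf, 1.0)
    np.testing.assert_array_equal(fs.pdf, 0.0)


def test_corrected_fit_reduces_to_uncensored(clean_truth, p_ref):
    df = generate_households(2000, clean_truth, seed=9)
    fs = {b: fit_first_stage(df, b) for b in BEVERAGES}
    assert all(not f.censored for f in fs.values())
    f_cor = fit_quaids(df, fs, alpha0=clean_truth.params.alpha0, p_ref=p_ref)
    f_unc = fit_quaids(df, None, alpha0=clean_truth.params.alpha0, p_ref=p_ref)
    np.testing.assert_allclose(f_cor.params.gamma, f_unc.params.gamma,
                               atol=1e-10)


def test_all_zero_outcome_degenerate(households_10k):
    df = households_10k.copy()
    df["qty_juice"] = 0.0
    with pytest.raises(DegenerateCensoringError):
        fit_first_stage(df, "juice")


def test_probit_coefficient_recovery(truth):
    """First-stage probit recovers the generator's censoring coefficients
    within 2 standard errors at n = 50,000."""
    df = generate_households(50_000, truth, seed=13)
    fs = fit_first_stage(df, "ssb")
    slopes = df.attrs["probit_slopes"]
    want = np.array([df.attrs["probit_intercepts"]["ssb"]]
                    + list(slopes.values()))
    z = np.abs(fs.params - want) / fs.bse
    # each coefficient within 3 SE, and the bulk within 2 SE (7 joint checks)
    assert np.all(z < 3.0), f"probit z-errors {z}"
    assert (z < 2.0).sum() >= 5


def test_intercept_only_limit(truth):
    """Censoring orthogonal to covariates: fitted probability matches the
    consuming fraction."""
    st = dataclasses.replace(truth.settings,
                             probit_slopes={}, consume_prob={"ssb": 0.7})
    t = dataclasses.replace(truth, settings=st)
    df = generate_households(20_000, t, seed=15)
    fs = fit_first_stage(df, "ssb")
    frac = (df.qty_ssb > 0).mean()
    assert fs.cdf.mean() == pytest.approx(frac, abs=0.005)


def test_two_step_recovers_ssb_elasticity(truth):
    """Point recovery on defaults at moderate n: the fitted SSB own-price
    elasticity is close to the generating value of -0.94."""
    df = generate_households(30_000, truth, seed=17)
    fit = two_step_fit(df)
    em = fit.elasticities()
    assert em.own_price("ssb") == pytest.approx(-0.94, abs=0.06)
    got = em.wrt_ssb_price()
    for b in ("milk", "juice", "tea"):
        assert got[b] > 0, f"substitution sign for {b}"


def test_fitted_system_satisfies_identities(truth):
    df = generate_households(15_000, truth, seed=19)
    em = two_step_fit(df).elasticities()
    np.testing.assert_allclose(em.shares @ em.marshallian + em.shares,
                               0.0, atol=1e-6)
    np.testing.assert_allclose(em.marshallian.sum(axis=1) + em.expenditure,
                               0.0, atol=1e-6)


def test_no_price_variation_rejected(households_10k):
    df = households_10k.copy()
    df["price_tea"] = 0.05
    with pytest.raises(ValueError, match="price variation"):
        fit_quaids(df, None)
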