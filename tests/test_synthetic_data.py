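"""Household and individual generators: calibration closure, censoring,
reproducibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ssbtax.synthetic import (default_ground_truth, generate_households,
                              generate_individuals)
from ssbtax.synthetic.households import InvalidParameterSet
from ssbtax.tables import BEVERAGES, cohort_row


# ---------------------------------------------------------------- households

def test_expenditure_identity(households_10k):
    total = sum(households_10k[f"price_{b}"] * households_10k[f"qty_{b}"]
                for b in BEVERAGES)
    np.testing.assert_allclose(total, households_10k.expenditure, rtol=1e-10)


def test_noise_free_records_lie_on_alpha_shares(clean_truth):
    """Zero noise, no censoring, degenerate price/outlay spread: every
    record's budget shares equal the truth's intercept shares."""
    st = dataclasses.replace(clean_truth.settings, price_log_sd=0.0,
                             outlay_log_sd=0.0, cohort_price_shift={})
    t = dataclasses.replace(clean_truth, settings=st)
    df = generate_households(10, t, seed=1)
    shares = np.column_stack([df[f"price_{b}"] * df[f"qty_{b}"] / df.outlay
                              for b in BEVERAGES])
    np.testing.assert_allclose(
        shares, np.tile(t.params.alpha[:5], (10, 1)), atol=1e-12)


def test_censoring_fraction_matches_binomial_oracle(truth):
    """Requested 30% SSB censoring is realised within binomial tolerance."""
    st = dataclasses.replace(truth.settings,
                             consume_prob={**truth.settings.consume_prob,
                                           "ssb": 0.7})
    t = dataclasses.replace(truth, settings=st)
    df = generate_households(100_000, t, seed=1)
    assert (df.qty_ssb == 0).mean() == pytest.approx(0.30, abs=0.01)


def test_censoring_monotonicity(truth):
    """Raising the censoring fraction never decreases the zero count."""
    counts = []
    for consume in (0.9, 0.7, 0.5):
        st = dataclasses.replace(truth.settings,
                                 consume_prob={"ssb": consume})
        t = dataclasses.replace(truth, settings=st)
        df = generate_households(20_000, t, seed=2)
        counts.append(int((df.qty_ssb == 0).sum()))
    assert counts[0] <= counts[1] <= counts[2]


def test_household_seed_reproducibility(truth):
    a = generate_households(500, truth, seed=42)
    b = generate_households(500, truth, seed=42)
    pd.testing.assert_frame_equal(a, b)
    c = generate_households(500, truth, seed=43)
    assert not a.equals(c)


def test_invalid_truth_rejected(truth):
    bad_params = dataclasses.replace(truth.params)
    bad_params.alpha = truth.params.alpha.copy()
    bad_params.alpha[1] = -0.5
    bad_params.alpha[5] += 0.5  # keep adding-up, shares go negative
    bad = dataclasses.replace(truth, params=bad_params)
    with pytest.raises(InvalidParameterSet):
        generate_households(100, bad, seed=0)


def test_price_band_respected(households_10k, truth):
    band = truth.settings.price_band
    med = truth.settings.median_prices["ssb"]
    ratio = households_10k.price_ssb / med
    # cohort medians shift by up to ~5%; the band applies around them
    assert ratio.min() > (1 - band) * 0.94
    assert ratio.max() < (1 + band) * 1.06


# --------------------------------------------------------------- individuals

@pytest.fixture(scope="module")
def overall_individuals():
    return generate_individuals(100_000, {"sex": "mixed"},
                                cohort_row("overall", "overall"), seed=1)


def test_mean_ssb_intake_calibrated(overall_individuals):
    assert overall_individuals.kcal_ssb.mean() == pytest.approx(46.0, abs=0.5)


def test_overweight_prevalence_calibrated(overall_individuals):
    assert (overall_individuals.bmi >= 25).mean() == pytest.approx(0.38,
                                                                   abs=0.01)


def test_all_beverage_means_calibrated(overall_individuals):
    row = cohort_row("overall", "overall")
    for b in BEVERAGES:
        got = overall_individuals[f"kcal_{b}"].mean()
        # 3-sigma Monte-Carlo closure at n = 1e5 with CV 0.5
        tol = 3 * row.kcal[b] * 0.5 / np.sqrt(len(overall_individuals))
        assert got == pytest.approx(row.kcal[b], abs=tol), b


def test_bmi_within_physiologic_range(overall_individuals):
    assert overall_individuals.bmi.between(12, 60).all()
    assert np.isfinite(overall_individuals.weight).all()


def test_zero_prevalence_target_truncates_below_threshold():
    row = dataclasses.replace(cohort_row("overall", "overall"),
                              overweight_prevalence=0.0)
    df = generate_individuals(5000, {"sex": "male"}, row, seed=3)
    assert (df.bmi < 25).all()


def test_infeasible_prevalence_rejected():
    row = dataclasses.replace(cohort_row("overall", "overall"),
                              overweight_prevalence=1.2)
    with pytest.raises(ValueError):
        generate_individuals(10, {"sex": "male"}, row, seed=0)


def test_intake_bmi_rank_correlation(overall_individuals):
    rho = spearmanr(overall_individuals.kcal_ssb,
                    overall_individuals.bmi).statistic
    assert 0.1 < rho < 0.3  # configured copula default 0.2


def test_individual_seed_reproducibility():
    row = cohort_row("residence", "urban")
    a = generate_individuals(300, {"residence": "urban"}, row, seed=9)
    b = generate_individuals(300, {"residence": "urban"}, row, seed=9)
    pd.testing.assert_frame_equal(a, b)
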