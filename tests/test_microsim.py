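"""Cohort microsimulation: pairing, calibration raking, uncertainty."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ssbtax.microsim import (ParameterBundle, build_cohorts, cases_averted,
                             cohort_populations, margin_reductions,
                             overall_outcomes, relative_reduction, run_paired,
                             run_scenario, uncertainty_run)
from ssbtax.tables import cohort_row


@pytest.fixture(scope="module")
def cohorts_small():
    return build_cohorts(200)


@pytest.fixture(scope="module")
def paired_small(cohorts_small):
    return run_paired(cohorts_small, tax_rate=0.20, seed=3)


def test_design_is_full_cross(cohorts_small):
    assert len(cohorts_small) == 24
    keys = {c.key for c in cohorts_small}
    assert len(keys) == 24
    assert sum(c.weight for c in cohorts_small) == pytest.approx(1.0)


def test_raking_reproduces_overall_margins(cohorts_small):
    """Weighted cell calibrations reproduce the overall baseline row."""
    overall = cohort_row("overall", "overall")
    w = np.array([c.weight for c in cohorts_small])
    for b in ("milk", "ssb", "tea"):
        got = sum(c.weight * c.row.kcal[b] for c in cohorts_small)
        assert got == pytest.approx(overall.kcal[b], rel=1e-9)
    prev = sum(c.weight * c.row.overweight_prevalence for c in cohorts_small)
    assert prev == pytest.approx(overall.overweight_prevalence, rel=1e-9)
    inc = sum(c.weight * c.row.diabetes_incidence for c in cohorts_small)
    assert inc == pytest.approx(overall.diabetes_incidence, rel=1e-9)


def test_zero_tax_run_is_identical_to_baseline(cohorts_small):
    """Null intervention with common seeds reproduces the baseline run
    exactly (common-random-number pairing)."""
    base = run_scenario(cohorts_small[:4], tax_rate=None, seed=11)
    null = run_scenario(cohorts_small[:4], tax_rate=0.0, seed=11)
    pd.testing.assert_frame_equal(base, null)


def test_seed_reproducibility(cohorts_small):
    a = run_scenario(cohorts_small[:2], tax_rate=0.2, seed=21)
    b = run_scenario(cohorts_small[:2], tax_rate=0.2, seed=21)
    pd.testing.assert_frame_equal(a, b)


def test_tax_reduces_both_outcomes(paired_small):
    base, taxed = paired_small
    assert relative_reduction(base, taxed, "overweight_prevalence") > 0
    assert relative_reduction(base, taxed, "diabetes_incidence") > 0


def test_ceiling_cohort_stays_overweight(cohorts_small):
    """A cohort initialised essentially entirely above the BMI threshold
    keeps prevalence ~ 1 regardless of the tax."""
    c = cohorts_small[0]
    row = dataclasses.replace(c.row, overweight_prevalence=0.999)
    ceiling = dataclasses.replace(c, row=row, n=400)
    taxed = run_scenario([ceiling], tax_rate=0.30, seed=5)
    assert (taxed.overweight_prevalence > 0.99).all()


def test_dose_response_monotone_in_tax(cohorts_small):
    base = run_scenario(cohorts_small, tax_rate=None, seed=7)
    effects = []
    for tau in (0.10, 0.20, 0.30):
        t = run_scenario(cohorts_small, tax_rate=tau, seed=7)
        effects.append(relative_reduction(base, t, "overweight_prevalence"))
    assert effects[0] < effects[1] < effects[2]


def test_common_random_numbers_reduce_contrast_variance(cohorts_small):
    """Paired contrasts vary less across seeds than mismatched-seed
    contrasts of the same scenarios."""
    sub = cohorts_small[:4]
    seeds = [101, 102, 103, 104, 105]
    runs_b = {s: overall_outcomes(run_scenario(sub, tax_rate=None, seed=s))
              for s in seeds}
    runs_t = {s: overall_outcomes(run_scenario(sub, tax_rate=0.2, seed=s))
              for s in seeds}
    col = "overweight_prevalence"
    last = max(runs_b[seeds[0]].index)
    paired = [runs_b[s].loc[last, col] - runs_t[s].loc[last, col]
              for s in seeds]
    crossed = [runs_b[s].loc[last, col] - runs_t[s2].loc[last, col]
               for s in seeds for s2 in seeds if s2 != s]
    assert np.var(paired) < np.var(crossed)


def test_margin_reductions_cover_all_levels(paired_small):
    base, taxed = paired_small
    red = margin_reductions(base, taxed)
    assert len(red) == 9
    assert set(k.split(":")[0] for k in red.index) == {
        "age", "sex", "income", "residence"}


def test_uncertainty_degenerate_zero_width(cohorts_small):
    """No parameter sampling and fixed inner seeds: every draw identical,
    hence zero-width intervals."""
    sub = cohorts_small[:3]
    out = uncertainty_run(sub, tax_rate=0.2, n_outer=2, seed=5,
                          sample_parameters=False, reseed_draws=False)
    s = out["summary"]
    assert s.loc["ci_low", "overweight_reduction_pct"] == pytest.approx(
        s.loc["ci_high", "overweight_reduction_pct"])


def test_uncertainty_interval_covers_central_estimate(cohorts_small):
    sub = cohorts_small[:6]
    out = uncertainty_run(sub, tax_rate=0.2, n_outer=8, seed=9)
    base, taxed = run_paired(sub, tax_rate=0.2, seed=9)
    point = relative_reduction(base, taxed, "overweight_prevalence")
    s = out["summary"]
    assert (s.loc["ci_low", "overweight_reduction_pct"] <= point
            <= s.loc["ci_high", "overweight_reduction_pct"])


def test_parameter_sampling_perturbs_inputs(cohorts_small):
    bundle = ParameterBundle()
    rng = np.random.default_rng(0)
    b2, c2 = bundle.sample(rng, cohorts_small[:2])
    assert b2.hazard.relative_risk != bundle.hazard.relative_risk
    assert b2.nutrients.gl_per_kcal["ssb"] != bundle.nutrients.gl_per_kcal["ssb"]
    assert c2[0].row.kcal["ssb"] != cohorts_small[0].row.kcal["ssb"]
    # sign constraints respected
    assert b2.hazard.relative_risk > 1.0
    assert all(v > 0 for v in b2.nutrients.gl_per_kcal.values())


def test_cases_averted_trivia(paired_small, cohorts_small):
    base, taxed = paired_small
    zero_pop = {c.key: 0.0 for c in cohorts_small}
    out = cases_averted(base, taxed, zero_pop)
    assert out["overweight_averted"] == 0.0
    same = cases_averted(base, base, cohort_populations(cohorts_small))
    assert same["diabetes_averted"] == 0.0
    with pytest.raises(KeyError):
        cases_averted(base, taxed, {"nope": 1.0})


def test_cases_averted_positive_at_scale(paired_small, cohorts_small):
    base, taxed = paired_small
    out = cases_averted(base, taxed, cohort_populations(cohorts_small))
    assert out["overweight_averted"] > 0
    assert out["diabetes_averted"] > 0
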