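"""Synthetic individual health records (anthropometry, intake, diabetes).

Emulates a migration-study-style individual dataset: the joint distribution
of height, weight/BMI, per-beverage energy intake and diabetes status,
calibrated so that cohort means of intake and the overweight fraction hit the
packaged baseline table.  BMI is right-skewed (lognormal) with the log-mean
solved from the cohort's overweight prevalence at the BMI >= 25 threshold;
intake is coupled to BMI through a Gaussian copula with a configurable rank
correlation (heavier consumers tend to be heavier people, but the data do not
pin the strength of that dependence down).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from ..tables import BEVERAGES, BeverageRow

__all__ = ["generate_individuals"]

OVERWEIGHT_BMI = 25.0

_HEIGHT = {"male": (1.65, 0.07), "female": (1.52, 0.065)}


class CalibrationError(ValueError):
    pass


def generate_individuals(n: int,
                         cohort: dict[str, str],
                         calibration: BeverageRow,
                         seed: int = 0,
                         *,
                         bmi_log_sd: float = 0.17,
                         intake_cv: float = 0.5,
                         intake_bmi_rank_corr: float = 0.2,
                         diabetes_prevalence: float | None = None,
                         activity_sd: float = 0.1) -> pd.DataFrame:
    """Draw ``n`` adults for one cohort; deterministic given ``seed``.

    ``cohort`` carries the labels (age band, sex, income tertile, residence);
    when sex is not fixed by the cohort it is mixed at the population ratio.
    ``diabetes_prevalence`` defaults to a baseline prevalence scaled from the
    cohort's incidence relative to the overall rate (initial prevalent cases
    are excluded from at-risk denominators downstream, so this mainly sizes
    the at-risk pool).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prev = calibration.overweight_prevalence
    if not 0.0 <= prev < 1.0:
        raise CalibrationError(
            f"overweight prevalence {prev} outside [0, 1)")
    rng = np.random.default_rng(seed)

    sex_label = cohort.get("sex")
    if sex_label in ("male", "female"):
        sex = np.full(n, sex_label)
    else:
        sex = np.where(rng.random(n) < 0.515, "male", "female")
    hm, hs = np.vectorize(lambda s: _HEIGHT[s])(sex)
    height = rng.normal(hm.astype(float), hs.astype(float))
    height = np.clip(height, 1.30, 2.05)

    # Gaussian copula: one latent factor for BMI, correlated latents per beverage
    u_bmi = rng.standard_normal(n)
    rho = intake_bmi_rank_corr
    if prev <= 0.0:
        # degenerate target: truncate the reference distribution below the threshold
        sigma = bmi_log_sd
        mu = np.log(OVERWEIGHT_BMI) - 2.0 * sigma
        cap = norm.cdf((np.log(OVERWEIGHT_BMI) - mu) / sigma)
        u = norm.cdf(u_bmi) * cap
        bmi = np.exp(mu + sigma * norm.ppf(u))
    else:
        sigma = bmi_log_sd
        mu = np.log(OVERWEIGHT_BMI) - sigma * norm.ppf(1.0 - prev)
        bmi = np.exp(mu + sigma * u_bmi)
    bmi = np.clip(bmi, 12.0, 60.0)
    weight = bmi * height ** 2

    data = {"age_band": np.full(n, cohort.get("age", "25-44")),
            "sex": sex,
            "income": np.full(n, cohort.get("income", "mid")),
            "residence": np.full(n, cohort.get("residence", "urban")),
            "height": height, "weight": weight, "bmi": bmi}

    sigma_i = np.sqrt(np.log1p(intake_cv ** 2))
    for b in BEVERAGES:
        mean_b = calibration.kcal[b]
        e = rng.standard_normal(n)
        u = rho * u_bmi + np.sqrt(1.0 - rho ** 2) * e
        if mean_b <= 0:
            data[f"kcal_{b}"] = np.zeros(n)
            continue
        mu_b = np.log(mean_b) - 0.5 * sigma_i ** 2
        data[f"kcal_{b}"] = np.exp(mu_b + sigma_i * u)

    if diabetes_prevalence is None:
        diabetes_prevalence = float(np.clip(
            0.08 * calibration.diabetes_incidence / 307.0, 0.0, 0.30))
    data["diabetes"] = rng.random(n) < diabetes_prevalence
    data["activity"] = np.clip(rng.normal(1.0, activity_sd, size=n), 0.7, 1.3)

    df = pd.DataFrame(data)
    df.attrs["seed"] = seed
    df.attrs["cohort"] = dict(cohort)
    return df
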