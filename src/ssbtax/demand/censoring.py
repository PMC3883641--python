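"""First stage of the two-step censored demand estimator.

Zero purchases are common in household expenditure records (a household that
bought no SSBs in the reference week reports a zero, not a negative demand).
The two-step correction first fits a probit of the consumption indicator on
household covariates, then enters the fitted probability Phi-hat as a
multiplier on the share equation and the density phi-hat as an additional
regressor, so the second stage remains consistent under censoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["FirstStage", "fit_first_stage", "DegenerateCensoringError",
           "COVARIATES"]

#: Covariate columns used by the consumption probit (plus an intercept).
COVARIATES = ("household_size", "age_head", "availability",
              "urban", "income_mid", "income_high")


class DegenerateCensoringError(ValueError):
    """All-zero / all-positive outcomes or complete separation."""


@dataclass
class FirstStage:
    """Per-beverage probit results evaluated on the estimation sample."""

    beverage: str
    params: np.ndarray | None      # None when the beverage is never censored
    cdf: np.ndarray                # Phi-hat per record
    pdf: np.ndarray                # phi-hat per record
    bse: np.ndarray | None = None
    censored: bool = True


def design_matrix(records: pd.DataFrame,
                  covariates: tuple[str, ...] = COVARIATES) -> np.ndarray:
    cols = [np.ones(len(records))]
    cols += [records[c].to_numpy(dtype=float) for c in covariates]
    return np.column_stack(cols)


def fit_first_stage(records: pd.DataFrame, beverage: str,
                    covariates: tuple[str, ...] = COVARIATES) -> FirstStage:
    """Probit of 1{quantity > 0} on covariates for one beverage.

    A beverage that every household consumes needs no correction: Phi = 1 and
    phi = 0, which reduces the corrected share equation to the uncensored
    one.  An all-zero outcome (or complete separation) leaves the demand for
    that beverage unidentified and raises :class:`DegenerateCensoringError`.
    """
    y = (records[f"qty_{beverage}"].to_numpy(dtype=float) > 0).astype(float)
    n = len(y)
    if y.sum() == n:
        return FirstStage(beverage, None, np.ones(n), np.zeros(n), censored=False)
    if y.sum() == 0:
        raise DegenerateCensoringError(f"no household consumes {beverage}")
    X = design_matrix(records, covariates)
    try:
        res = sm.Probit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise DegenerateCensoringError(
            f"probit failed for {beverage}: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise DegenerateCensoringError(f"non-finite probit fit for {beverage}")
    xb = X @ res.params
    from scipy.stats import norm
    return FirstStage(beverage, res.params, norm.cdf(xb), norm.pdf(xb),
                      bse=res.bse, censored=True)
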