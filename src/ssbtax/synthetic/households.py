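"""Synthetic household beverage-expenditure records.

Emulates a national consumer-expenditure survey: per-household quantities and
unit prices for five beverage classes plus total outlay, with regional price
variation, zero-consumption censoring and demographic covariates.  Records
are drawn from a known QUAIDS ground truth so the demand estimator can be
validated by parameter recovery; the packaged default truth is constructed so
that its implied elasticities at the median-price / median-outlay point equal
the packaged elasticity table's overall column exactly.

Censoring is generated independently of the share disturbance (a latent
probit propensity decides whether a household participates in each beverage
market), so the two-step estimator's density-term coefficients are truly zero
and consistency of the corrected fit can be checked directly.  Expenditure a
household does not spend on a censored beverage flows to the composite
outside good, preserving adding-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from ..demand.quaids import DemandParameters, ElasticityMatrix, budget_shares, elasticities
from ..tables import BEVERAGES, GOODS, elasticity_vector, load_generator_settings

__all__ = ["GroundTruth", "GeneratorSettings", "default_ground_truth",
           "generate_households", "InvalidParameterSet"]


class InvalidParameterSet(ValueError):
    """The demand truth implies shares outside [0, 1] at sampled prices."""


@dataclass
class GeneratorSettings:
    """Sampling configuration for the household generator."""

    median_prices: dict[str, float]
    outlay_median: float = 60.0
    outlay_log_sd: float = 0.25
    price_log_sd: float = 0.09
    price_band: float = 0.175          # +-17.5% band => 35% total range
    other_price_band: float = 0.05
    share_noise_sd: float = 0.003
    consume_prob: dict[str, float] = field(default_factory=dict)
    probit_slopes: dict[str, float] = field(default_factory=dict)
    cohort_price_shift: dict[str, float] = field(default_factory=dict)
    urban_share: float = 0.40
    income_probs: tuple[float, float, float] = (0.28, 0.505, 0.215)


@dataclass
class GroundTruth:
    """Demand parameters plus the sampling settings used to generate data."""

    params: DemandParameters
    settings: GeneratorSettings

    def implied_elasticities(self) -> ElasticityMatrix:
        """Elasticities at median prices and median outlay."""
        lnx = self.params.alpha0  # alpha0 is set to log median outlay
        return elasticities(self.params, np.zeros(len(GOODS)), lnx)

    def censoring_probabilities(self) -> dict[str, float]:
        return {b: 1.0 - self.settings.consume_prob.get(b, 1.0)
                for b in BEVERAGES}


def build_demand_parameters(raw: dict) -> DemandParameters:
    """Assemble a constraint-satisfying QUAIDS truth from generator settings.

    The SSB column of the price-coefficient matrix is solved so that the
    Marshallian elasticities wrt SSB price at the evaluation point equal the
    packaged overall elasticity column; the non-SSB block is filled from
    configured own-price elasticities and small cross terms, and the outside
    good's row/column follow from homogeneity and adding-up.
    """
    goods = list(raw["goods"])
    assert tuple(goods) == GOODS
    G = len(goods)
    alpha = np.array(raw["alpha"], dtype=float)
    if abs(alpha.sum() - 1) > 1e-12 or np.any(alpha <= 0):
        raise InvalidParameterSet("alpha must be positive and sum to 1")

    eta = raw["expenditure_elasticity"]
    beta = np.zeros(G)
    for i, b in enumerate(BEVERAGES):
        beta[i] = alpha[i] * (eta[i] - 1.0)
    beta[G - 1] = -beta[:G - 1].sum()

    lam = np.zeros(G)
    for i in range(len(BEVERAGES)):
        lam[i] = raw["lambda"][i]
    lam[G - 1] = -lam[:G - 1].sum()

    e_ssb = elasticity_vector("overall", "overall")
    s = goods.index("ssb")
    gamma = np.zeros((G, G))
    # SSB column from the target elasticities: e_iS = (gamma_iS - beta_i*alpha_S)/alpha_i - 1{i=S}
    for i, b in enumerate(BEVERAGES):
        target = float(e_ssb[b])
        gamma[i, s] = alpha[i] * (target + (1.0 if i == s else 0.0)) + beta[i] * alpha[s]
    gamma[G - 1, s] = -gamma[:G - 1, s].sum()
    gamma[s, :] = gamma[:, s]
    # non-SSB beverage diagonal from configured own-price elasticities
    for b, e_own in raw["own_price_elasticity_non_ssb"].items():
        i = goods.index(b)
        gamma[i, i] = alpha[i] * (e_own + 1.0) + beta[i] * alpha[i]
    # small substitution terms among the non-SSB beverages
    for key, val in raw["gamma_cross_non_ssb"].items():
        a, b = key.split(",")
        i, j = goods.index(a), goods.index(b)
        gamma[i, j] = gamma[j, i] = float(val)
    # homogeneity fixes each beverage's outside-good entry; adding-up the corner
    o = G - 1
    for i in range(len(BEVERAGES)):
        gamma[i, o] = -gamma[i, :o].sum()
        gamma[o, i] = gamma[i, o]
    gamma[o, o] = -gamma[o, :o].sum()

    params = DemandParameters(
        alpha=alpha, beta=beta, lam=lam, gamma=gamma,
        alpha0=float(np.log(raw["outlay_median"])), goods=GOODS)
    params.validate(tol=1e-10)
    return params


def default_ground_truth() -> GroundTruth:
    raw = load_generator_settings()
    params = build_demand_parameters(raw)
    settings = GeneratorSettings(
        median_prices=dict(raw["median_prices"]),
        outlay_median=raw["outlay_median"],
        outlay_log_sd=raw["outlay_log_sd"],
        price_log_sd=raw["price_log_sd"],
        price_band=raw["price_band"],
        other_price_band=raw["other_price_band"],
        share_noise_sd=raw["share_noise_sd"],
        consume_prob=dict(raw["censoring"]["consume_prob"]),
        probit_slopes=dict(raw["censoring"]["coefficients"]),
        cohort_price_shift=dict(raw["cohort_price_shift"]),
    )
    return GroundTruth(params=params, settings=settings)


def _truncated_lognormal(rng, n, log_sd, band):
    """exp(eps), eps ~ N(0, log_sd) truncated to |ratio - 1| <= band."""
    if log_sd == 0 or band == 0:
        return np.ones(n)
    lo, hi = np.log1p(-band), np.log1p(band)
    a, b = lo / log_sd, hi / log_sd
    return np.exp(truncnorm.rvs(a, b, scale=log_sd, size=n, random_state=rng))


def generate_households(n: int, truth: GroundTruth | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` household records from the ground truth; seed-deterministic.

    The returned frame's ``attrs`` record the seed and the first-stage probit
    intercepts solved for this sample (slopes come from the truth), so probit
    recovery can be tested against known coefficients.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    truth = truth or default_ground_truth()
    st = truth.settings
    rng = np.random.default_rng(seed)
    G = len(GOODS)

    income = rng.choice(np.array(["low", "mid", "high"]), size=n,
                        p=np.array(st.income_probs) / sum(st.income_probs))
    urban = rng.random(n) < st.urban_share
    household_size = 1 + rng.poisson(3.5, size=n)
    age_head = np.clip(rng.normal(45, 12, size=n), 18, 90)
    availability = rng.random(n)

    shift = np.zeros(n)
    shift += np.where(urban, st.cohort_price_shift.get("urban", 0.0), 0.0)
    shift += np.where(income == "low", st.cohort_price_shift.get("income_low", 0.0), 0.0)
    shift += np.where(income == "high", st.cohort_price_shift.get("income_high", 0.0), 0.0)

    prices = np.empty((n, G))
    for j, g in enumerate(GOODS):
        band = st.other_price_band if g == "other" else st.price_band
        ratio = _truncated_lognormal(rng, n, st.price_log_sd
                                     if g != "other" else st.price_log_sd / 2,
                                     band)
        base = st.median_prices[g] * (1.0 + (shift if g != "other" else 0.0))
        prices[:, j] = base * ratio

    outlay = st.outlay_median * np.exp(rng.normal(0.0, st.outlay_log_sd, size=n))

    p_ref = np.array([st.median_prices[g] for g in GOODS])
    q = np.log(prices / p_ref[None, :])
    w_latent = budget_shares(truth.params, q, np.log(outlay))
    if np.any(w_latent < 0) or np.any(w_latent > 1):
        raise InvalidParameterSet(
            "truth implies shares outside [0, 1] at sampled prices")
    if st.share_noise_sd > 0:
        noise = rng.normal(0.0, st.share_noise_sd, size=(n, G - 1))
        w = w_latent.copy()
        w[:, :G - 1] = np.clip(w_latent[:, :G - 1] + noise, 0.0, 1.0)
        w[:, G - 1] = 1.0 - w[:, :G - 1].sum(axis=1)
    else:
        w = w_latent

    # latent consumption propensity: fixed slopes, intercept solved on this
    # sample so the realised consuming fraction matches the configured target
    z = np.column_stack([household_size.astype(float), age_head, availability,
                         urban.astype(float), (income == "mid").astype(float),
                         (income == "high").astype(float)])
    slope_names = ("household_size", "age_head", "availability", "urban",
                   "income_mid", "income_high")
    slopes = np.array([st.probit_slopes.get(k, 0.0) for k in slope_names])
    zb = z @ slopes
    intercepts = {}
    consumed = np.ones((n, len(BEVERAGES)), dtype=bool)
    for i, b in enumerate(BEVERAGES):
        target = st.consume_prob.get(b, 1.0)
        if target >= 1.0:
            intercepts[b] = None
            continue
        if not 0.0 < target < 1.0:
            raise ValueError(f"consume probability for {b} must be in (0, 1]")
        c0 = brentq(lambda c: norm.cdf(c + zb).mean() - target, -30, 30)
        intercepts[b] = float(c0)
        consumed[:, i] = rng.random(n) < norm.cdf(c0 + zb)

    w_obs = w.copy()
    w_obs[:, :len(BEVERAGES)] *= consumed
    w_obs[:, G - 1] = 1.0 - w_obs[:, :G - 1].sum(axis=1)

    qty = w_obs[:, :len(BEVERAGES)] * outlay[:, None] / prices[:, :len(BEVERAGES)]
    df = pd.DataFrame({"household_id": np.arange(n)})
    df["income"] = income
    df["residence"] = np.where(urban, "urban", "rural")
    for i, b in enumerate(BEVERAGES):
        df[f"qty_{b}"] = qty[:, i]
        df[f"price_{b}"] = prices[:, i]
    df["price_other"] = prices[:, G - 1]
    df["outlay"] = outlay
    df["expenditure"] = (qty * prices[:, :len(BEVERAGES)]).sum(axis=1)
    df["household_size"] = household_size
    df["age_head"] = age_head
    df["availability"] = availability
    df["urban"] = urban.astype(int)
    df["income_mid"] = (income == "mid").astype(int)
    df["income_high"] = (income == "high").astype(int)
    df.attrs["seed"] = seed
    df.attrs["probit_intercepts"] = intercepts
    df.attrs["probit_slopes"] = dict(zip(slope_names, slopes))
    return df
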