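"""Quadratic Almost Ideal Demand System: shares, price indices, elasticities.

The system models budget shares over the five beverage classes plus a
composite outside good (everything else the household buys, including the
option of leaving the purchased-beverage market).  Shares follow

    w_i = alpha_i + sum_j gamma_ij ln p_j + beta_i ln(x/a(p))
          + lambda_i / b(p) * [ln(x/a(p))]^2

with the translog price index ln a(p) = alpha_0 + sum alpha_i ln p_i
+ 1/2 sum_ij gamma_ij ln p_i ln p_j and the Cobb-Douglas aggregator
b(p) = prod p_i^beta_i.  Adding-up, homogeneity and Slutsky symmetry are
imposed exactly on the coefficient arrays.

Prices enter normalised by a reference (median) price vector, so ``ln p``
below always means ``ln(p / p_ref)``; the normalisation only relabels the
intercepts and is recorded alongside fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..tables import GOODS

__all__ = ["DemandParameters", "ElasticityMatrix", "budget_shares", "elasticities"]


@dataclass
class DemandParameters:
    """QUAIDS coefficient bundle for ``len(goods)`` goods.

    alpha : intercept shares, sums to 1.
    beta : expenditure slopes, sums to 0.
    lam : quadratic expenditure slopes, sums to 0.
    gamma : symmetric price-coefficient matrix with zero row sums.
    alpha0 : translog intercept (log outlay scale anchor).
    """

    alpha: np.ndarray
    beta: np.ndarray
    lam: np.ndarray
    gamma: np.ndarray
    alpha0: float = 0.0
    goods: tuple[str, ...] = GOODS
    first_stage_coefs: dict | None = None

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)

    def validate(self, tol: float = 1e-8) -> None:
        """Check adding-up, homogeneity and symmetry to ``tol``."""
        if abs(self.alpha.sum() - 1.0) > tol:
            raise ValueError("adding-up violated: sum(alpha) != 1")
        if abs(self.beta.sum()) > tol or abs(self.lam.sum()) > tol:
            raise ValueError("adding-up violated: sum(beta) or sum(lambda) != 0")
        if np.abs(self.gamma.sum(axis=1)).max() > tol:
            raise ValueError("homogeneity violated: gamma row sums != 0")
        if np.abs(self.gamma - self.gamma.T).max() > tol:
            raise ValueError("Slutsky symmetry violated")

    def index(self, good: str) -> int:
        return self.goods.index(good)


def log_price_index(params: DemandParameters, lnp: np.ndarray) -> np.ndarray:
    """Translog ln a(p) for an (n, G) array of normalised log prices."""
    lnp = np.atleast_2d(lnp)
    quad = 0.5 * np.einsum("ni,ij,nj->n", lnp, params.gamma, lnp)
    return params.alpha0 + lnp @ params.alpha + quad


def cobb_douglas_deflator(params: DemandParameters, lnp: np.ndarray) -> np.ndarray:
    """b(p) = prod p_i^beta_i on normalised prices."""
    lnp = np.atleast_2d(lnp)
    return np.exp(lnp @ params.beta)


def budget_shares(params: DemandParameters, lnp: np.ndarray,
                  lnx: np.ndarray) -> np.ndarray:
    """Model budget shares, shape (n, G).  Shares sum to 1 by construction."""
    lnp = np.atleast_2d(lnp)
    lnx = np.atleast_1d(lnx)
    z = lnx - log_price_index(params, lnp)
    b = cobb_douglas_deflator(params, lnp)
    w = (params.alpha[None, :] + lnp @ params.gamma.T
         + params.beta[None, :] * z[:, None]
         + params.lam[None, :] * (z ** 2 / b)[:, None])
    return w


@dataclass
class ElasticityMatrix:
    """Marshallian and expenditure elasticities at one evaluation point.

    ``marshallian[i, j]`` is the % change in good i per 1% change in the
    price of good j; ``expenditure[i]`` per 1% change in total outlay.
    Optional bootstrap percentile CIs share the same layout.
    """

    goods: tuple[str, ...]
    marshallian: np.ndarray
    expenditure: np.ndarray
    shares: np.ndarray
    lnp: np.ndarray
    lnx: float
    marshallian_ci: np.ndarray | None = None  # (2, G, G) low/high
    expenditure_ci: np.ndarray | None = None  # (2, G)
    meta: dict = field(default_factory=dict)

    def own_price(self, good: str) -> float:
        i = self.goods.index(good)
        return float(self.marshallian[i, i])

    def cross(self, good: str, price_of: str) -> float:
        return float(self.marshallian[self.goods.index(good),
                                      self.goods.index(price_of)])

    def wrt_ssb_price(self) -> pd.Series:
        """The reported column: beverage elasticities wrt the SSB price."""
        j = self.goods.index("ssb")
        bev = [g for g in self.goods if g != "other"]
        return pd.Series({g: self.marshallian[self.goods.index(g), j] for g in bev})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.marshallian, index=list(self.goods),
                          columns=list(self.goods))
        df["expenditure"] = self.expenditure
        return df


def elasticities(params: DemandParameters, lnp: np.ndarray,
                 lnx: float) -> ElasticityMatrix:
    """Point elasticities from the standard QUAIDS derivative formulas.

    Raises if any model share at the point is outside (0, 1), where the
    share-normalised elasticity is undefined.
    """
    lnp = np.asarray(lnp, dtype=float).reshape(1, -1)
    w = budget_shares(params, lnp, np.array([lnx]))[0]
    if np.any(w <= 0) or np.any(w >= 1):
        bad = [g for g, s in zip(params.goods, w) if s <= 0 or s >= 1]
        raise ValueError(f"elasticity undefined: share outside (0,1) for {bad}")
    z = float(lnx - log_price_index(params, lnp)[0])
    b = float(cobb_douglas_deflator(params, lnp)[0])
    mu = params.beta + 2.0 * params.lam / b * z
    # d ln a / d ln p_j
    dlna = params.alpha + params.gamma @ lnp[0]
    mu_ij = (params.gamma
             - np.outer(mu, dlna)
             - np.outer(params.lam, params.beta) * z ** 2 / b)
    G = len(params.goods)
    marsh = mu_ij / w[:, None] - np.eye(G)
    eta = 1.0 + mu / w
    return ElasticityMatrix(goods=params.goods, marshallian=marsh,
                            expenditure=eta, shares=w, lnp=lnp[0], lnx=lnx)
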