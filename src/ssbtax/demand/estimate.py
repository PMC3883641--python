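"""Censored QUAIDS estimation on household expenditure records.

Strategy: for fixed price indices a(p), b(p) the share system is linear in
(alpha, gamma, beta, lambda, delta), so the constrained fit is an iterated
linear least-squares problem.  Adding-up, homogeneity and symmetry are
imposed by estimating only a free sub-vector and reconstructing the full
coefficient arrays; one share equation is excluded from the objective (the
composite outside good by default) and recovered through adding-up.  The
censoring correction multiplies each beverage's share equation by its
first-stage consumption probability and adds the first-stage density as a
regressor.

Confidence intervals come from a nonparametric bootstrap over households,
re-running both stages on each resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..tables import BEVERAGES, GOODS
from .censoring import FirstStage, fit_first_stage
from .quaids import DemandParameters, ElasticityMatrix, elasticities

__all__ = ["fit_quaids", "bootstrap_elasticities", "QuaidsFit",
           "ConvergenceError", "prepare_arrays"]

_B = len(BEVERAGES)          # 5 beverage equations
_G = len(GOODS)              # 6 goods including the outside composite
_PAIRS = [(k, l) for k in range(_B) for l in range(k, _B)]
_PAIR_INDEX = {p: i for i, p in enumerate(_PAIRS)}


class ConvergenceError(RuntimeError):
    def __init__(self, msg, iterations=None, last_change=None, params=None):
        super().__init__(msg)
        self.iterations = iterations
        self.last_change = last_change
        self.params = params


@dataclass
class QuaidsFit:
    params: DemandParameters
    iterations: int
    converged: bool
    objective: float
    p_ref: np.ndarray
    lnx_eval: float
    first_stage: dict[str, FirstStage] | None
    delta: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def elasticities(self) -> ElasticityMatrix:
        """Elasticities at the reference prices / median outlay point."""
        return elasticities(self.params, np.zeros(_G), self.lnx_eval)


def prepare_arrays(records: pd.DataFrame, p_ref: np.ndarray | None = None):
    """Shares, normalised log prices and log outlay from a household frame."""
    prices = np.column_stack(
        [records[f"price_{b}"].to_numpy(float) for b in BEVERAGES]
        + [records["price_other"].to_numpy(float)])
    if p_ref is None:
        p_ref = np.median(prices, axis=0)
    q = np.log(prices / p_ref[None, :])
    x = records["outlay"].to_numpy(float)
    lnx = np.log(x)
    w_bev = np.column_stack(
        [records[f"price_{b}"].to_numpy(float)
         * records[f"qty_{b}"].to_numpy(float) / x for b in BEVERAGES])
    w = np.column_stack([w_bev, 1.0 - w_bev.sum(axis=1)])
    return w, q, lnx, p_ref


def _free_to_full(theta: np.ndarray, delta_goods: list[int]):
    a = np.empty(_G)
    a[:_B] = theta[0:_B]
    a[_B] = 1.0 - a[:_B].sum()
    b = np.empty(_G)
    b[:_B] = theta[_B:2 * _B]
    b[_B] = -b[:_B].sum()
    l = np.empty(_G)
    l[:_B] = theta[2 * _B:3 * _B]
    l[_B] = -l[:_B].sum()
    g = np.zeros((_G, _G))
    off = 3 * _B
    for idx, (k, m) in enumerate(_PAIRS):
        g[k, m] = g[m, k] = theta[off + idx]
    g[:_B, _B] = -g[:_B, :_B].sum(axis=1)
    g[_B, :_B] = g[:_B, _B]
    g[_B, _B] = -g[_B, :_B].sum()
    delta = np.zeros(_B)
    off2 = off + len(_PAIRS)
    for j, gi in enumerate(delta_goods):
        delta[gi] = theta[off2 + j]
    return a, b, l, g, delta


def _full_to_free(params: DemandParameters, delta: np.ndarray,
                  delta_goods: list[int]) -> np.ndarray:
    parts = [params.alpha[:_B], params.beta[:_B], params.lam[:_B],
             np.array([params.gamma[k, m] for k, m in _PAIRS]),
             delta[delta_goods]]
    return np.concatenate(parts)


def fit_quaids(records: pd.DataFrame,
               first_stage: dict[str, FirstStage] | None = None,
               *,
               drop: str = "other",
               alpha0: float | None = None,
               p_ref: np.ndarray | None = None,
               tol: float = 1e-8,
               max_iter: int = 500) -> QuaidsFit:
    """Fit the censored QUAIDS by iterated constrained linear least squares.

    Parameters
    ----------
    records : household frame with ``qty_*``, ``price_*``, ``price_other``,
        ``outlay`` and the probit covariates.
    first_stage : per-beverage probit results; ``None`` treats every
        beverage as uncensored (Phi = 1).
    drop : which share equation to exclude from the objective; with the
        symmetry/adding-up constraints imposed the estimates are invariant
        to this choice.  Must be ``"other"`` when censoring corrections are
        present (the corrected beverage equations no longer share an exact
        adding-up identity with the outside equation).
    alpha0 : translog intercept; defaults to log median outlay so the
        quadratic expenditure term is centred on the data.
    """
    for b in BEVERAGES:
        v = records[f"price_{b}"].to_numpy(float)
        if np.ptp(np.log(v)) <= 0:
            raise ValueError(f"no price variation for {b}")
    w, q, lnx, p_ref = prepare_arrays(records, p_ref)
    n = len(records)
    if alpha0 is None:
        alpha0 = float(np.median(lnx))

    censored_any = first_stage is not None and any(
        fs.censored for fs in first_stage.values())
    if censored_any and drop != "other":
        raise ValueError("with censoring corrections the outside-good "
                         "equation must be the dropped one")
    Phi = np.ones((n, _B))
    phi = np.zeros((n, _B))
    if first_stage is not None:
        for i, b in enumerate(BEVERAGES):
            fs = first_stage.get(b)
            if fs is not None:
                Phi[:, i] = fs.cdf
                phi[:, i] = fs.pdf
    delta_goods = [i for i in range(_B)
                   if first_stage is not None
                   and first_stage.get(BEVERAGES[i]) is not None
                   and first_stage[BEVERAGES[i]].censored]

    equations = [g for g in range(_G) if GOODS[g] != drop]
    if len(equations) != _G - 1:
        raise ValueError(f"unknown equation to drop: {drop!r}")

    qstar = q[:, :_B] - q[:, _B:_B + 1]
    n_free = 3 * _B + len(_PAIRS) + len(delta_goods)

    # initial iterate: intercept-only system at observed mean shares
    alpha = w.mean(axis=0)
    alpha = alpha / alpha.sum()
    params = DemandParameters(alpha=alpha, beta=np.zeros(_G),
                              lam=np.zeros(_G), gamma=np.zeros((_G, _G)),
                              alpha0=alpha0)
    theta = _full_to_free(params, np.zeros(_B), delta_goods)

    converged = False
    it = 0
    change = np.inf
    for it in range(1, max_iter + 1):
        lna = (params.alpha0 + q @ params.alpha
               + 0.5 * np.einsum("ni,ij,nj->n", q, params.gamma, q))
        z = lnx - lna
        bdef = np.exp(q @ params.beta)
        z2b = z ** 2 / bdef

        ATA = np.zeros((n_free, n_free))
        ATb = np.zeros(n_free)
        for i in equations:
            if i < _B:
                cols = [i, _B + i, 2 * _B + i]
                mats = [Phi[:, i], Phi[:, i] * z, Phi[:, i] * z2b]
                for j in range(_B):
                    cols.append(3 * _B + _PAIR_INDEX[(min(i, j), max(i, j))])
                    mats.append(Phi[:, i] * qstar[:, j])
                if i in delta_goods:
                    cols.append(3 * _B + len(_PAIRS) + delta_goods.index(i))
                    mats.append(phi[:, i])
                y = w[:, i]
            else:  # outside-good equation (uncensored by construction)
                cols = (list(range(_B)) + list(range(_B, 2 * _B))
                        + list(range(2 * _B, 3 * _B)))
                mats = [-np.ones(n) for _ in range(_B)]
                mats += [-z for _ in range(_B)]
                mats += [-z2b for _ in range(_B)]
                gcols, gmats = [], []
                for idx, (k, m) in enumerate(_PAIRS):
                    gcols.append(3 * _B + idx)
                    if k == m:
                        gmats.append(-qstar[:, k])
                    else:
                        gmats.append(-(qstar[:, k] + qstar[:, m]))
                cols += gcols
                mats += gmats
                y = w[:, i] - 1.0
            L = np.column_stack(mats)
            idx = np.asarray(cols)
            ATA[np.ix_(idx, idx)] += L.T @ L
            ATb[idx] += L.T @ y

        try:
            theta_new = np.linalg.solve(ATA, ATb)
        except np.linalg.LinAlgError:
            theta_new = np.linalg.lstsq(ATA, ATb, rcond=None)[0]

        change = float(np.max(np.abs(theta_new - theta)))
        theta = theta_new
        a_, b_, l_, g_, delta = _free_to_full(theta, delta_goods)
        params = DemandParameters(alpha=a_, beta=b_, lam=l_, gamma=g_,
                                  alpha0=alpha0)
        if change < tol:
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"QUAIDS fit did not converge in {max_iter} iterations "
            f"(last parameter change {change:.3e})",
            iterations=it, last_change=change, params=params)

    # objective at the solution
    lna = (params.alpha0 + q @ params.alpha
           + 0.5 * np.einsum("ni,ij,nj->n", q, params.gamma, q))
    z = lnx - lna
    bdef = np.exp(q @ params.beta)
    wfit = (params.alpha[None, :] + q @ params.gamma.T
            + params.beta[None, :] * z[:, None]
            + params.lam[None, :] * (z ** 2 / bdef)[:, None])
    resid = 0.0
    for i in equations:
        if i < _B:
            pred = Phi[:, i] * wfit[:, i] + delta[i] * phi[:, i]
        else:
            pred = wfit[:, i]
        resid += float(np.sum((w[:, i] - pred) ** 2))

    params.first_stage_coefs = (
        {b: None if first_stage is None or first_stage.get(b) is None
         else first_stage[b].params for b in BEVERAGES}
        if first_stage is not None else None)
    return QuaidsFit(params=params, iterations=it, converged=converged,
                     objective=resid, p_ref=p_ref,
                     lnx_eval=float(np.median(lnx)),
                     first_stage=first_stage, delta=delta,
                     meta={"drop": drop, "n": n})


def two_step_fit(records: pd.DataFrame, **kw) -> QuaidsFit:
    """Convenience wrapper: probit first stage for every beverage with any
    zeros, then the corrected share-system fit."""
    fs = {}
    for b in BEVERAGES:
        fs[b] = fit_first_stage(records, b)
    return fit_quaids(records, fs, **kw)


def bootstrap_elasticities(records: pd.DataFrame, *, n_boot: int = 200,
                           seed: int = 0, alpha0: float | None = None,
                           progress: bool = False) -> ElasticityMatrix:
    """Point elasticities with household-bootstrap percentile CIs.

    The evaluation point (reference median prices, median log outlay) is
    fixed at the full-sample values so replicates differ only through the
    estimated coefficients.
    """
    fit = two_step_fit(records, alpha0=alpha0)
    point = fit.elasticities()
    rng = np.random.default_rng(seed)
    n = len(records)
    marsh = np.empty((n_boot, _G, _G))
    eta = np.empty((n_boot, _G))
    kept = 0
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = records.iloc[idx].reset_index(drop=True)
        try:
            f = two_step_fit(sample, alpha0=alpha0, p_ref=fit.p_ref)
            e = elasticities(f.params, np.zeros(_G), fit.lnx_eval)
        except Exception:
            continue
        marsh[kept] = e.marshallian
        eta[kept] = e.expenditure
        kept += 1
    if kept < max(10, n_boot // 2):
        raise ConvergenceError(
            f"too many bootstrap failures ({kept}/{n_boot} usable)")
    lo, hi = np.percentile(marsh[:kept], [2.5, 97.5], axis=0)
    elo, ehi = np.percentile(eta[:kept], [2.5, 97.5], axis=0)
    point.marshallian_ci = np.stack([lo, hi])
    point.expenditure_ci = np.stack([elo, ehi])
    point.meta.update({"n_boot": kept, "seed": seed,
                       "marshallian_se": marsh[:kept].std(axis=0, ddof=1),
                       "expenditure_se": eta[:kept].std(axis=0, ddof=1)})
    return point
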