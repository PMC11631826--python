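"""Comparator estimators: selection-on-observables and linear IV.

These are the analyses a study team would run alongside the local-IV
estimator: inverse-probability-of-treatment weighting with regression
adjustment (IPTW-RA, doubly robust under no unobserved confounding),
classical two-stage least squares, the Wald ratio between two instrument
levels, and naive OLS.  Under essential heterogeneity the linear IV
estimators identify instrument-weighted averages of marginal effects
rather than the ATE; contrasting them with the local-IV estimate is the
point of including them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .liv_core import ModelSpec, TermSet, _probit_mle

__all__ = [
    "PotentialOutcomePredictions",
    "LinearIVEstimate",
    "iptw_ra",
    "two_stage_least_squares",
    "wald_late",
    "naive_ols",
]

WEIGHT_CAP = 50.0


@dataclass
class PotentialOutcomePredictions:
    """Recycled predictions from the weighted outcome model."""

    y1_hat: np.ndarray
    y0_hat: np.ndarray
    effect: np.ndarray
    weights: np.ndarray
    n_truncated: int
    ate: float


@dataclass
class LinearIVEstimate:
    point: float
    se: float
    ci_low: float
    ci_high: float
    first_stage_f: float | None = None
    weak_instrument: bool = False
    method: str = "2SLS"


def _covariate_design(cohort: pd.DataFrame, terms: TermSet | None) -> tuple[np.ndarray, ModelSpec]:
    spec = ModelSpec(terms or TermSet(iv_interactions=()), cohort)
    Xc, _ = spec.covariate_block(cohort)
    return Xc, spec


def iptw_ra(
    cohort: pd.DataFrame,
    terms: TermSet | None = None,
    outcome_terms: TermSet | None = None,
    weight_cap: float = WEIGHT_CAP,
    weighting: bool = True,
) -> PotentialOutcomePredictions:
    """IPTW with regression adjustment and recycled predictions.

    The treatment model is a probit on covariates only — the instrument
    is deliberately excluded, since this comparator represents the
    "no unobserved confounding" analysis.  Stabilised inverse-probability
    weights (capped, truncations counted) enter a weighted
    gaussian-identity outcome regression with a full set of
    treatment x covariate interactions; recycled predictions under both
    assignments give individual effects, whose mean is the doubly robust
    ATE.

    ``outcome_terms`` lets the outcome regression use a different
    covariate set from the treatment model (the double-robustness
    property concerns exactly this case); ``weighting=False`` drops the
    weights, reducing the estimator to plain regression adjustment.
    """
    Xt, _ = _covariate_design(cohort, terms)
    Xc, _spec = _covariate_design(
        cohort, outcome_terms if outcome_terms is not None else terms
    )
    d = cohort["D"].to_numpy(float)
    y = cohort["Y"].to_numpy(float)
    beta_t = _probit_mle(Xt, d)
    ps = np.clip(ndtr(Xt @ beta_t), 1e-3, 1 - 1e-3)
    p_marg = d.mean()
    w = np.where(d == 1, p_marg / ps, (1 - p_marg) / (1 - ps))
    n_trunc = int((w > weight_cap).sum())
    w = np.minimum(w, weight_cap)
    if not weighting:
        w = np.ones_like(w)
        n_trunc = 0

    # fully interacted outcome model: y ~ Xc + D + D:(Xc minus constant)
    X_out = np.column_stack([Xc, d[:, None], d[:, None] * Xc[:, 1:]])
    sw = np.sqrt(w)
    beta = np.linalg.lstsq(X_out * sw[:, None], y * sw, rcond=None)[0]
    k = Xc.shape[1]
    beta_base, beta_d, beta_int = beta[:k], beta[k], beta[k + 1:]
    y0_hat = Xc @ beta_base
    y1_hat = y0_hat + beta_d + Xc[:, 1:] @ beta_int
    effect = y1_hat - y0_hat
    return PotentialOutcomePredictions(
        y1_hat=y1_hat, y0_hat=y0_hat, effect=effect, weights=w,
        n_truncated=n_trunc, ate=float(effect.mean()),
    )


def _cluster_cov(Xh: np.ndarray, resid: np.ndarray, groups: np.ndarray,
                 bread_inv: np.ndarray) -> np.ndarray:
    """CR1 cluster-robust covariance."""
    n, k = Xh.shape
    scores = Xh * resid[:, None]
    order = np.argsort(groups, kind="stable")
    g_sorted = groups[order]
    s_sorted = scores[order]
    edges = np.flatnonzero(np.r_[True, g_sorted[1:] != g_sorted[:-1], True])
    G = len(edges) - 1
    meat = np.zeros((k, k))
    for a, b in zip(edges[:-1], edges[1:]):
        sg = s_sorted[a:b].sum(axis=0)
        meat += np.outer(sg, sg)
    cr1 = (G / (G - 1)) * ((n - 1) / (n - k))
    return cr1 * bread_inv @ meat @ bread_inv


def two_stage_least_squares(
    cohort: pd.DataFrame,
    terms: TermSet | None = None,
    alpha: float = 0.05,
) -> LinearIVEstimate:
    """Linear 2SLS of the outcome on treatment (instrumented) and covariates,
    with region-clustered (CR1) standard errors.

    A first-stage cluster-robust F below 10 flags the estimate as
    weak-instrument."""
    z = cohort["Z"].to_numpy(float)
    if np.ptp(z) == 0:
        raise ValueError("no instrument variation: Z is constant")
    Xc, _ = _covariate_design(cohort, terms)
    d = cohort["D"].to_numpy(float)
    y = cohort["Y"].to_numpy(float)
    groups = cohort["region_id"].to_numpy()

    X = np.column_stack([Xc, d])
    W = np.column_stack([Xc, z])
    # project the endogenous columns on the instrument set
    coef_w, *_ = np.linalg.lstsq(W, X, rcond=None)
    Xh = W @ coef_w
    XtX = Xh.T @ X
    beta = np.linalg.solve(XtX, Xh.T @ y)
    resid = y - X @ beta
    bread_inv = np.linalg.inv(XtX)
    V = _cluster_cov(Xh, resid, groups, bread_inv)
    j = X.shape[1] - 1
    se = float(np.sqrt(V[j, j]))
    point = float(beta[j])

    # first-stage strength, same cluster correction
    gamma = np.linalg.lstsq(W, d, rcond=None)[0]
    fs_resid = d - W @ gamma
    WtW_inv = np.linalg.inv(W.T @ W)
    Vf = _cluster_cov(W, fs_resid, groups, WtW_inv)
    jz = W.shape[1] - 1
    f_stat = float(gamma[jz] ** 2 / Vf[jz, jz])
    weak = f_stat < 10.0
    if weak:
        warnings.warn(f"weak first stage: cluster-robust F = {f_stat:.2f} < 10",
                      stacklevel=2)
    from scipy.stats import norm

    zc = norm.ppf(1 - alpha / 2)
    return LinearIVEstimate(
        point=point, se=se, ci_low=point - zc * se, ci_high=point + zc * se,
        first_stage_f=f_stat, weak_instrument=weak, method="2SLS",
    )


def wald_late(
    cohort: pd.DataFrame,
    z_low,
    z_high,
    covariate_cell=None,
) -> LinearIVEstimate:
    """Wald ratio between two instrument levels within a covariate cell.

    ``z_low`` / ``z_high`` are boolean masks selecting the two instrument
    groups; ``covariate_cell`` optionally restricts both.  Returns
    ``[E(Y|high) - E(Y|low)] / [E(D|high) - E(D|low)]`` with a
    delta-method standard error.
    """
    lo = np.asarray(z_low, bool)
    hi = np.asarray(z_high, bool)
    if covariate_cell is not None:
        cell = np.asarray(covariate_cell, bool)
        lo, hi = lo & cell, hi & cell
    if lo.sum() == 0 or hi.sum() == 0:
        raise ValueError("empty instrument group within the covariate cell")
    y = cohort["Y"].to_numpy(float)
    d = cohort["D"].to_numpy(float)
    dy = y[hi].mean() - y[lo].mean()
    dd = d[hi].mean() - d[lo].mean()
    if dd == 0:
        raise ValueError("no compliers at these instrument levels (zero denominator)")
    late = dy / dd

    var = 0.0
    for mask in (hi, lo):
        n_g = mask.sum()
        vy = y[mask].var(ddof=1) / n_g
        vd = d[mask].var(ddof=1) / n_g
        cyd = np.cov(y[mask], d[mask], ddof=1)[0, 1] / n_g
        var += (vy - 2 * late * cyd + late**2 * vd) / dd**2
    se = float(np.sqrt(max(var, 0.0)))
    return LinearIVEstimate(
        point=float(late), se=se, ci_low=float(late - 1.96 * se),
        ci_high=float(late + 1.96 * se), method="Wald-LATE",
    )


def naive_ols(cohort: pd.DataFrame, terms: TermSet | None = None) -> LinearIVEstimate:
    """Covariate-adjusted OLS of the outcome on treatment; biased under
    unobserved confounding, included as the reference point the IV
    estimators are judged against."""
    Xc, _ = _covariate_design(cohort, terms)
    d = cohort["D"].to_numpy(float)
    y = cohort["Y"].to_numpy(float)
    X = np.column_stack([Xc, d])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, k = X.shape
    sigma2 = resid @ resid / (n - k)
    V = sigma2 * np.linalg.inv(X.T @ X)
    j = k - 1
    se = float(np.sqrt(V[j, j]))
    point = float(beta[j])
    return LinearIVEstimate(point=point, se=se, ci_low=point - 1.96 * se,
                            ci_high=point + 1.96 * se, method="OLS")
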