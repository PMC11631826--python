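"""Local-instrumental-variable estimator of marginal and personalised effects.

The estimator follows the two-stage local IV recipe for a continuous
preference instrument:

1. a probit model of treatment on covariates and the instrument gives
   each patient's propensity ``p_hat``;
2. the outcome is regressed (gaussian, identity link) on covariates, a
   polynomial in ``p_hat`` and selected ``p_hat x covariate``
   interactions;
3. the marginal treatment effect (MTE) at ``(x, p)`` is the analytic
   derivative of the fitted outcome surface with respect to ``p``;
4. personalised effects (PeT) integrate the MTE over the latent
   resistance values compatible with each patient's covariates,
   instrument level and observed treatment, using one shared vector of
   uniform draws over the estimated propensity support.

Interaction and quadratic terms are chosen once per analysis by a
plugin-penalty ("rigorous") LASSO run on each stage, keeping the union
of terms selected in either stage and using it identically in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import ndtr, ndtri
from sklearn.linear_model import Lasso

__all__ = [
    "TermSet",
    "ModelSpec",
    "PropensityFit",
    "OutcomeFit",
    "PeTResult",
    "SeparationError",
    "select_terms_lasso",
    "select_specification",
    "fit_propensity",
    "fit_outcome",
    "mte",
    "pet_effects",
    "dstar_assignment",
]

P_CLIP = 1e-3

CONTINUOUS = ("age", "hba1c", "bmi", "egfr", "sbp", "dbp", "duration")

DEFAULT_MAINS = (
    "age", "female", "eth_south_asian", "eth_black_mixed_other",
    "hba1c", "bmi", "egfr", "sbp", "dbp", "duration",
)


class SeparationError(RuntimeError):
    """Probit coefficients diverged; the treatment is (quasi-)separated."""


@dataclass(frozen=True)
class TermSet:
    """Candidate or selected model terms shared by the two stages.

    ``iv_interactions`` lists covariates interacted with the instrument
    in stage 1 and with the propensity in stage 2 — selection treats the
    pair as one term.  Main effects, the instrument (stage 1) and the
    propensity polynomial (stage 2) are forced and never penalized.
    """

    main_terms: tuple = DEFAULT_MAINS
    quadratic_terms: tuple = ("age_sq", "hba1c_sq")
    covariate_interactions: tuple = ("hba1c_x_age", "hba1c_x_female", "hba1c_x_bmi")
    iv_interactions: tuple = ("hba1c", "egfr", "bmi", "sbp", "age")
    pscore_poly_degree: int = 3

    def penalized_keys(self) -> tuple:
        return (
            tuple(self.quadratic_terms)
            + tuple(self.covariate_interactions)
            + tuple(f"iv_x_{c}" for c in self.iv_interactions)
        )

    def restrict(self, keys: set) -> "TermSet":
        return replace(
            self,
            quadratic_terms=tuple(t for t in self.quadratic_terms if t in keys),
            covariate_interactions=tuple(
                t for t in self.covariate_interactions if t in keys
            ),
            iv_interactions=tuple(
                c for c in self.iv_interactions if f"iv_x_{c}" in keys
            ),
        )


class ModelSpec:
    """Builds stage-1 and stage-2 design matrices for a term set.

    Continuous covariates are standardised with mean/SD taken from the
    estimation sample at construction, so bootstrap refits reuse the same
    column definitions.
    """

    def __init__(self, terms: TermSet, cohort: pd.DataFrame):
        self.terms = terms
        self.scales = {
            c: (float(cohort[c].mean()), float(cohort[c].std(ddof=0)) or 1.0)
            for c in CONTINUOUS
        }

    # -- column primitives -------------------------------------------------
    def _col(self, df: pd.DataFrame, name: str) -> np.ndarray:
        if name in CONTINUOUS:
            m, s = self.scales[name]
            return (df[name].to_numpy(float) - m) / s
        if name == "female":
            return df["female"].to_numpy(float)
        if name == "eth_south_asian":
            return (df["ethnicity"] == "south_asian").to_numpy(float)
        if name == "eth_black_mixed_other":
            return (df["ethnicity"] == "black_mixed_other").to_numpy(float)
        raise KeyError(f"unknown design column {name!r}")

    def _base_term(self, df: pd.DataFrame, key: str) -> np.ndarray:
        if key.endswith("_sq"):
            v = self._col(df, key[:-3])
            return v * v
        if "_x_" in key and not key.startswith("iv_x_"):
            a, b = key.split("_x_")
            return self._col(df, a) * self._col(df, b)
        return self._col(df, key)

    def covariate_block(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Constant, main effects, quadratics and covariate interactions —
        identical in both stages."""
        names = ["const", *self.terms.main_terms, *self.terms.quadratic_terms,
                 *self.terms.covariate_interactions]
        cols = [np.ones(len(df))]
        cols += [self._base_term(df, k) for k in names[1:]]
        return np.column_stack(cols), names

    def iv_block(self, df: pd.DataFrame, driver: np.ndarray) -> tuple[np.ndarray, list[str]]:
        """Interactions of the instrument (stage 1) or propensity (stage 2)
        with the selected covariates."""
        names = [f"iv_x_{c}" for c in self.terms.iv_interactions]
        if not names:
            return np.empty((len(df), 0)), names
        cols = [driver * self._col(df, c) for c in self.terms.iv_interactions]
        return np.column_stack(cols), names

    def stage1_design(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        Xc, names = self.covariate_block(df)
        z = df["Z"].to_numpy(float)
        Xi, inames = self.iv_block(df, z)
        return np.column_stack([Xc, z[:, None], Xi]), names + ["Z"] + inames

    def interaction_values(self, df: pd.DataFrame) -> np.ndarray:
        """Standardised covariate values entering the p_hat interactions
        (needed for the analytic MTE)."""
        if not self.terms.iv_interactions:
            return np.empty((len(df), 0))
        return np.column_stack([self._col(df, c) for c in self.terms.iv_interactions])


class PScorePoly:
    """Orthogonalised polynomial basis in the propensity with an analytic
    derivative.

    The raw power basis [p, p^2, ..., p^k] is centred and QR-orthogonalised
    on the estimation sample (improving the conditioning of the outcome
    regression); the stored triangular transform maps derivative
    evaluations into the same basis.
    """

    def __init__(self, p_hat: np.ndarray, degree: int):
        if degree < 1:
            raise ValueError("pscore_poly_degree must be >= 1")
        self.degree = degree
        V = np.column_stack([p_hat**k for k in range(1, degree + 1)])
        self.means = V.mean(axis=0)
        _, R = np.linalg.qr(V - self.means)
        scale = np.sqrt(len(p_hat))
        self.transform = linalg.solve_triangular(R, np.eye(degree) * scale)

    def basis(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_1d(np.asarray(p, float))
        V = np.column_stack([p**k for k in range(1, self.degree + 1)])
        return (V - self.means) @ self.transform

    def deriv(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_1d(np.asarray(p, float))
        dV = np.column_stack([k * p ** (k - 1) for k in range(1, self.degree + 1)])
        return dV @ self.transform


@dataclass
class PropensityFit:
    params: pd.Series
    p_hat: np.ndarray
    support: tuple
    spec: ModelSpec


@dataclass
class OutcomeFit:
    params: pd.Series
    poly: PScorePoly
    spec: ModelSpec
    support: tuple
    beta_poly: np.ndarray = field(init=False)
    beta_iv: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.beta_poly = self.params[
            [f"phat_{k}" for k in range(1, self.poly.degree + 1)]
        ].to_numpy()
        self.beta_iv = self.params[
            [f"iv_x_{c}" for c in self.spec.terms.iv_interactions]
        ].to_numpy()

    def mte_curve(self, p: np.ndarray) -> np.ndarray:
        """Covariate-free part of the MTE: derivative of the propensity
        polynomial."""
        return self.poly.deriv(p) @ self.beta_poly

    def mte_shift(self, df: pd.DataFrame) -> np.ndarray:
        """Per-patient covariate contribution to the MTE from the
        p_hat x covariate interactions."""
        W = self.spec.interaction_values(df)
        return W @ self.beta_iv if W.size else np.zeros(len(df))


@dataclass
class PeTResult:
    """Per-patient personalised effects and the shared integration draws.

    ``pet_effect`` is the branch mean consistent with the observed
    treatment; ``branch_treated`` / ``branch_untreated`` hold both branch
    means and ``draw_weight`` the fraction of draws below each patient's
    propensity, so the exact aggregation identity
    ``w * treated + (1 - w) * untreated = mean MTE over all draws``
    can be verified draw-for-draw.
    """

    pet_effect: np.ndarray
    side: np.ndarray  # "treated" / "untreated" integration branch
    n_draws_used: np.ndarray
    branch_treated: np.ndarray
    branch_untreated: np.ndarray
    draw_weight: np.ndarray
    u_draws: np.ndarray
    seed: int | None
    n_fallback: int


# ---------------------------------------------------------------------------
# probit first stage
# ---------------------------------------------------------------------------

def _probit_mle(X: np.ndarray, d: np.ndarray, max_iter: int = 60, tol: float = 1e-10):
    """Newton-Raphson probit maximum likelihood.

    A lean implementation used in bootstrap inner loops; agreement with
    statsmodels' Probit is covered by a unit test.
    """
    n, k = X.shape
    beta = np.zeros(k)
    # start from the linear-probability projection for robustness
    beta = np.linalg.lstsq(X, (d - d.mean()) * 2.5, rcond=None)[0]
    beta[0] += ndtri(np.clip(d.mean(), 1e-6, 1 - 1e-6))
    for _ in range(max_iter):
        xb = X @ beta
        if np.max(np.abs(xb)) > 40 or np.max(np.abs(beta)) > 1e4:
            raise SeparationError(
                "probit index diverged: treatment appears separated in these "
                "covariates; review the generating process or term set"
            )
        p = np.clip(ndtr(xb), 1e-12, 1 - 1e-12)
        phi = np.exp(-0.5 * xb**2) / np.sqrt(2 * np.pi)
        # score and expected information (Fisher scoring)
        w = phi**2 / (p * (1 - p))
        resid = (d - p) / (p * (1 - p)) * phi
        grad = X.T @ resid
        XW = X * w[:, None]
        H = X.T @ XW
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular probit information matrix: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise SeparationError("probit did not converge; possible separation")
    return beta


def fit_propensity(cohort: pd.DataFrame, terms: TermSet | None = None,
                   spec: ModelSpec | None = None) -> PropensityFit:
    """Probit propensity for treatment given covariates and the instrument.

    Fitted probabilities are clipped to ``[1e-3, 1 - 1e-3]`` and the
    observed support ``(min p_hat, max p_hat)`` is recorded; the PeT
    integration draws from this support.
    """
    if spec is None:
        spec = ModelSpec(terms or TermSet(), cohort)
    d = cohort["D"].to_numpy(float)
    if d.min() == d.max():
        raise ValueError("degenerate treatment: all D identical")
    X, names = spec.stage1_design(cohort)
    beta = _probit_mle(X, d)
    p_hat = np.clip(ndtr(X @ beta), P_CLIP, 1 - P_CLIP)
    return PropensityFit(
        params=pd.Series(beta, index=names),
        p_hat=p_hat,
        support=(float(p_hat.min()), float(p_hat.max())),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# gaussian-identity outcome stage
# ---------------------------------------------------------------------------

def _stage2_design(spec: ModelSpec, cohort: pd.DataFrame, p_hat: np.ndarray,
                   poly: PScorePoly) -> tuple[np.ndarray, list[str]]:
    Xc, names = spec.covariate_block(cohort)
    B = poly.basis(p_hat)
    pnames = [f"phat_{k}" for k in range(1, poly.degree + 1)]
    Xi, inames = spec.iv_block(cohort, p_hat)
    return np.column_stack([Xc, B, Xi]), names + pnames + inames


def fit_outcome(cohort: pd.DataFrame, p_hat: np.ndarray,
                terms: TermSet | None = None,
                spec: ModelSpec | None = None,
                support: tuple | None = None) -> OutcomeFit:
    """Gaussian identity-link regression of the outcome on covariates, an
    orthogonalised polynomial in the propensity, and propensity-covariate
    interactions."""
    if spec is None:
        spec = ModelSpec(terms or TermSet(), cohort)
    y = cohort["Y"].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite outcome values present; run the complete-case filter first")
    poly = PScorePoly(p_hat, spec.terms.pscore_poly_degree)
    X, names = _stage2_design(spec, cohort, p_hat, poly)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via the QR diagonal
        R = np.linalg.qr(X, mode="r")
        bad = [names[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"outcome design is rank deficient; aliased columns: {bad}")
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    if support is None:
        support = (float(p_hat.min()), float(p_hat.max()))
    return OutcomeFit(params=pd.Series(beta, index=names), poly=poly, spec=spec,
                      support=support)


def mte(outcome_fit: OutcomeFit, x: dict | pd.DataFrame, p,
        extrapolate: bool = False) -> float | np.ndarray:
    """Marginal treatment effect at covariate profile ``x`` and propensity
    quantile ``p``: the analytic derivative of the fitted outcome surface.

    ``x`` is a mapping (or one-row frame) of raw covariate values for the
    covariates in the selected propensity interactions.
    """
    p_arr = np.atleast_1d(np.asarray(p, float))
    lo, hi = outcome_fit.support
    if not extrapolate and (p_arr.min() < lo - 1e-12 or p_arr.max() > hi + 1e-12):
        raise ValueError(
            f"p={p} outside the fitted propensity support ({lo:.4f}, {hi:.4f}); "
            "pass extrapolate=True to evaluate anyway"
        )
    if isinstance(x, dict):
        x = pd.DataFrame([x])
    shift = float(outcome_fit.mte_shift(x)[0]) if len(x) else 0.0
    vals = outcome_fit.mte_curve(p_arr) + shift
    return float(vals[0]) if np.isscalar(p) or np.asarray(p).ndim == 0 else vals


def dstar_assignment(p_hat: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Latent treatment rule on the draw grid: D* = Phi^{-1}(p_hat) + Phi^{-1}(1-u),
    positive where the draw is consistent with choosing treatment.

    Returns a boolean (n_patients, n_draws) matrix ``D* > 0``; algebraically
    identical to ``u < p_hat``.
    """
    return (ndtri(p_hat)[:, None] + ndtri(1.0 - u)[None, :]) > 0


def pet_effects(prop_fit: PropensityFit, outcome_fit: OutcomeFit,
                cohort: pd.DataFrame, n_draws: int = 1000,
                seed: int | None = None,
                rng: np.random.Generator | None = None) -> PeTResult:
    """Personalised treatment effects by conditional numerical integration.

    One shared vector of ``n_draws`` uniform draws over the estimated
    propensity support is used for every patient; treated patients
    average the MTE over draws with ``u < p_hat`` (equivalently
    ``D* > 0``), untreated patients over the complement.  A patient whose
    propensity sits at the support edge and has no qualifying draw falls
    back to the nearest draw; such fallbacks are counted.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = prop_fit.support
    u = rng.uniform(lo, hi, n_draws)
    order = np.argsort(u)
    u_sorted = u[order]
    t = outcome_fit.mte_curve(u_sorted)
    prefix = np.concatenate([[0.0], np.cumsum(t)])
    total = prefix[-1]

    p_hat = prop_fit.p_hat
    d = cohort["D"].to_numpy()
    k = np.searchsorted(u_sorted, p_hat, side="left")  # draws strictly below p_hat

    treated = d == 1
    n_used = np.where(treated, k, n_draws - k)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_below = np.where(k > 0, prefix[k] / np.maximum(k, 1), t[0])
        mean_above = np.where(k < n_draws,
                              (total - prefix[k]) / np.maximum(n_draws - k, 1), t[-1])
    # support-edge fallback (no qualifying draw): nearest single draw
    fb = (treated & (k == 0)) | ((~treated) & (k == n_draws))
    n_used = np.where(fb, 1, n_used)

    shift = outcome_fit.mte_shift(cohort)
    branch_treated = mean_below + shift
    branch_untreated = mean_above + shift
    pet = np.where(treated, branch_treated, branch_untreated)
    side = np.where(treated, "treated", "untreated")
    return PeTResult(
        pet_effect=pet,
        side=side,
        n_draws_used=n_used.astype(np.int64),
        branch_treated=branch_treated,
        branch_untreated=branch_untreated,
        draw_weight=k / n_draws,
        u_draws=u,
        seed=seed,
        n_fallback=int(fb.sum()),
    )


# ---------------------------------------------------------------------------
# rigorous (plugin-penalty) LASSO term selection
# ---------------------------------------------------------------------------

def _rigorous_lasso_select(X_pen: np.ndarray, X_free: np.ndarray, y: np.ndarray,
                           c: float = 1.1, gamma: float | None = None,
                           n_iter: int = 4) -> np.ndarray:
    """Indices of penalized columns kept by a heteroscedasticity-robust
    plugin-penalty LASSO.

    Unpenalized columns are partialled out of the response and the
    penalized block; the penalty level is
    ``lambda = 2 c sqrt(n) Phi^{-1}(1 - gamma / (2 p))`` with loadings
    ``psi_j = sqrt(mean(x_j^2 e^2))`` iterated from the residuals.
    """
    n, p = X_pen.shape
    if p == 0:
        return np.array([], dtype=int)
    if gamma is None:
        gamma = 0.1 / np.log(max(n, 3))
    # partial out the forced block (Frisch-Waugh)
    coef_free, *_ = np.linalg.lstsq(X_free, np.column_stack([y[:, None], X_pen]), rcond=None)
    resid_all = np.column_stack([y[:, None], X_pen]) - X_free @ coef_free
    y_t, X_t = resid_all[:, 0], resid_all[:, 1:]
    sd = X_t.std(axis=0)
    if np.any(sd < 1e-12):
        bad = np.where(sd < 1e-12)[0]
        raise ValueError(
            f"candidate columns {bad.tolist()} are collinear with the forced terms"
        )
    X_t = X_t / sd
    lam = 2.0 * c * np.sqrt(n) * ndtri(1.0 - gamma / (2.0 * p))
    eps = y_t.copy()
    sel = np.array([], dtype=int)
    for _ in range(n_iter):
        psi = np.sqrt(np.mean(X_t**2 * eps[:, None] ** 2, axis=0))
        psi = np.maximum(psi, 1e-12)
        Xw = X_t / psi
        alpha = lam / (2.0 * n)
        model = Lasso(alpha=alpha, fit_intercept=False, max_iter=5000, tol=1e-8)
        model.fit(Xw, y_t)
        coef = model.coef_
        new_sel = np.where(np.abs(coef) > 1e-10)[0]
        # post-lasso residuals drive the next loadings
        if new_sel.size:
            b, *_ = np.linalg.lstsq(X_t[:, new_sel], y_t, rcond=None)
            eps = y_t - X_t[:, new_sel] @ b
        else:
            eps = y_t
        if np.array_equal(new_sel, sel):
            sel = new_sel
            break
        sel = new_sel
    return sel


def select_terms_lasso(cohort: pd.DataFrame, candidate: TermSet, stage: int,
                       p_hat: np.ndarray | None = None) -> set:
    """Keys of candidate terms kept by the plugin LASSO in one stage.

    Stage 1 regresses the treatment indicator (linear first stage, the
    standard device for selection with a binary treatment) on the
    candidates with the instrument and main effects forced; stage 2
    regresses the outcome with the propensity polynomial and main effects
    forced.  Returns candidate keys, with instrument/propensity
    interactions reported under their shared ``iv_x_*`` key.
    """
    spec = ModelSpec(candidate, cohort)
    keys = candidate.penalized_keys()
    if not keys:
        return set()
    if stage == 1:
        y = cohort["D"].to_numpy(float)
        # forced part: mains plus the instrument itself
        free_spec = ModelSpec(replace(candidate, quadratic_terms=(),
                                      covariate_interactions=(), iv_interactions=()),
                              cohort)
        X_free, _ = free_spec.covariate_block(cohort)
        X_free = np.column_stack([X_free, cohort["Z"].to_numpy(float)])
        driver = cohort["Z"].to_numpy(float)
    elif stage == 2:
        if p_hat is None:
            raise ValueError("stage 2 selection requires p_hat")
        y = cohort["Y"].to_numpy(float)
        free_spec = ModelSpec(replace(candidate, quadratic_terms=(),
                                      covariate_interactions=(), iv_interactions=()),
                              cohort)
        X_free, _ = free_spec.covariate_block(cohort)
        poly = PScorePoly(p_hat, candidate.pscore_poly_degree)
        X_free = np.column_stack([X_free, poly.basis(p_hat)])
        driver = p_hat
    else:
        raise ValueError("stage must be 1 or 2")

    pen_cols = []
    for key in keys:
        if key.startswith("iv_x_"):
            pen_cols.append(driver * spec._col(cohort, key[len("iv_x_"):]))
        else:
            pen_cols.append(spec._base_term(cohort, key))
    X_pen = np.column_stack(pen_cols)
    sel_idx = _rigorous_lasso_select(X_pen, X_free, y)
    return {keys[j] for j in sel_idx}


def select_specification(cohort: pd.DataFrame,
                         candidate: TermSet | None = None) -> TermSet:
    """Union-across-stages specification search.

    Runs the plugin LASSO on the treatment stage, fits the probit on the
    stage-1 selection to obtain propensities, runs the LASSO on the
    outcome stage, and keeps every candidate term selected in at least
    one stage.  The returned term set is used identically in both stages
    of the final fit (and frozen across bootstrap refits).
    """
    if candidate is None:
        candidate = TermSet()
    sel1 = select_terms_lasso(cohort, candidate, stage=1)
    stage1_terms = candidate.restrict(sel1)
    prop = fit_propensity(cohort, stage1_terms)
    sel2 = select_terms_lasso(cohort, candidate, stage=2, p_hat=prop.p_hat)
    return candidate.restrict(sel1 | sel2)
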