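"""The nine genomic-selection predictors and REML variance components.

Linear mixed-model predictors (rrBLUP, gBLUP) solve Henderson's
mixed-model equations; LASSO and Bayesian ridge shrink marker effects with
L1 and Gaussian priors; RKHS and support-vector regression operate on a
Gaussian kernel; boosting, bagging and stacking are ensemble learners over
regression trees and base-model predictions.  All fitters return a
:class:`ModelFit` with training-set GEBVs, marker effects where defined,
variance components where estimated, and their regularization parameters.

Variance components are estimated by restricted maximum likelihood for the
single-random-effect model y = 1*mu + g + e, g ~ N(0, K*sigma2_a), via the
spectral profile restricted likelihood: one eigendecomposition of the
projected kinship, then a 1-D search over the variance ratio
delta = sigma2_e / sigma2_a.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear, minimize_scalar
from sklearn.linear_model import Lasso, LassoCV
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from gsnue.kinship import KinshipMatrix

MODEL_NAMES = (
    "rrBLUP",
    "gBLUP",
    "LASSO",
    "BGLR",
    "RKHS",
    "SVM",
    "BOOST",
    "BAGG",
    "STACK",
)


class IdentifiabilityWarning(UserWarning):
    """Variance components are only weakly identified by the data."""


@dataclass
class VarianceComponents:
    """Additive genetic and residual variances on the trait-unit^2 scale."""

    sigma2_a: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be nonnegative")

    @property
    def h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        if tot <= 0:
            raise ValueError("both variance components are zero")
        return self.sigma2_a / tot

    @property
    def ratio(self) -> float:
        """lambda = sigma2_e / sigma2_a (infinite for a null genetic variance)."""
        if self.sigma2_a <= 0:
            return np.inf
        return self.sigma2_e / self.sigma2_a


@dataclass
class ModelFit:
    """One fitted GS predictor."""

    model: str
    gebv: np.ndarray
    intercept: float
    residuals: np.ndarray
    marker_effects: np.ndarray | None = None
    vc: VarianceComponents | None = None
    regularization: dict = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)
    state: dict = field(default_factory=dict)  # solver internals for predict()


def _as_matrix(K: KinshipMatrix | np.ndarray) -> np.ndarray:
    return K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def estimate_variance_components(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
    log10_delta_range: tuple[float, float] = (-6.0, 6.0),
) -> VarianceComponents:
    """Spectral REML for y = X b + g + e with g ~ N(0, K sigma2_a).

    The fixed-effect design X is the intercept plus optional ``covariates``
    (e.g. population-structure indicators).  The restricted likelihood
    projects out X, eigendecomposes the projected kinship once, and is
    profiled over delta = sigma2_e/sigma2_a on a log grid refined by bounded
    golden-section search.
    """
    y = np.asarray(y, dtype=float)
    A = _as_matrix(K)
    n = y.size
    if A.shape != (n, n):
        raise ValueError("kinship dimension does not match phenotype length")
    if y.var() <= 0:
        raise ValueError("phenotype has zero variance")

    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([X, C])
    # orthonormal basis of the fixed-effect space, rank-aware
    Q, R = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())))
    Q = Q[:, :rank]

    # project out the fixed effects, then eigendecompose the projected kinship
    S = np.eye(n) - Q @ Q.T
    yc = S @ y
    xi, U = np.linalg.eigh(S @ A @ S)
    # drop the eigenvalues belonging to the projected-out directions
    keep = np.argsort(xi)[rank:]
    xi = np.clip(xi[keep], 0.0, None)
    eta2 = (U[:, keep].T @ yc) ** 2
    nr = n - rank

    if np.ptp(xi) < 1e-8 * max(1.0, xi.max()):
        warnings.warn(
            "kinship eigenvalues are all equal (K ~ identity); sigma2_a and "
            "sigma2_e are not separately identifiable, returning a boundary fit",
            IdentifiabilityWarning,
        )

    def neg_restricted_ll(log10_delta: float) -> float:
        delta = 10.0**log10_delta
        w = xi + delta
        s2a = float(np.sum(eta2 / w) / nr)
        ll = -0.5 * (nr * np.log(s2a) + np.sum(np.log(w)))
        return -ll

    lo, hi = log10_delta_range
    grid = np.linspace(lo, hi, 61)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg_restricted_ll, bounds=(a, b), method="bounded")
    delta = 10.0**res.x
    s2a = float(np.sum(eta2 / (xi + delta)) / nr)
    s2e = float(delta * s2a)
    return VarianceComponents(sigma2_a=s2a, sigma2_e=s2e)


def snp_heritability(vc: VarianceComponents) -> float:
    """SNP heritability h2 = sigma2_a / (sigma2_a + sigma2_e)."""
    return vc.h2


# ---------------------------------------------------------------------------
# Linear mixed-model predictors
# ---------------------------------------------------------------------------


def fit_rrblup(
    y: np.ndarray,
    X: np.ndarray,
    lambda_: float | None = None,
    fit_intercept: bool = True,
    vc: VarianceComponents | None = None,
) -> ModelFit:
    """Ridge-regression BLUP of marker effects via the mixed-model equations.

    Solves [[1'1, 1'X], [X'1, X'X + lambda I]] [mu; g] = [1'y; X'y] with
    lambda = sigma2_e / sigma2_g from REML on the marker-derived GRM when not
    supplied.  GEBV = X g_hat.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    meta: dict = {}
    if lambda_ is None:
        from gsnue.kinship import build_grm

        G = build_grm(X)
        vc = vc or estimate_variance_components(y, G)
        denom = G.parameters["denominator"]
        # sigma2_g per marker: cov(Xg) = XX' sigma2_g = G * (denom * sigma2_g)
        ratio = vc.ratio
        lambda_ = ratio * denom if np.isfinite(ratio) else 1e8 * denom
        meta["reml_delta"] = ratio
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")

    if fit_intercept and m > n:
        # dual form via the Woodbury identity: (X'X + lam I)^{-1} X' =
        # X'(XX' + lam I)^{-1}; the GLS intercept uses the same n x n system
        H = X @ X.T + lambda_ * np.eye(n)
        Hinv = np.linalg.inv(H)
        ones = np.ones(n)
        mu = float(ones @ Hinv @ y / (ones @ Hinv @ ones))
        g = X.T @ (Hinv @ (y - mu))
        gebv = X @ g
        return ModelFit(
            model="rrBLUP",
            gebv=gebv,
            intercept=mu,
            residuals=y - mu - gebv,
            marker_effects=g,
            vc=vc,
            regularization={"lambda": float(lambda_)},
            training_meta=meta,
        )

    XtX = X.T @ X
    if fit_intercept:
        A = np.empty((m + 1, m + 1))
        A[0, 0] = n
        A[0, 1:] = X.sum(axis=0)
        A[1:, 0] = X.sum(axis=0)
        A[1:, 1:] = XtX + lambda_ * np.eye(m)
        rhs = np.concatenate(([y.sum()], X.T @ y))
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"singular MME system: {err}") from err
        mu, g = float(sol[0]), sol[1:]
    else:
        sol = np.linalg.solve(XtX + lambda_ * np.eye(m), X.T @ y)
        mu, g = 0.0, sol
    gebv = X @ g
    return ModelFit(
        model="rrBLUP",
        gebv=gebv,
        intercept=mu,
        residuals=y - mu - gebv,
        marker_effects=g,
        vc=vc,
        regularization={"lambda": float(lambda_)},
        training_meta=meta,
    )


def fit_gblup(
    y: np.ndarray,
    G: KinshipMatrix | np.ndarray,
    lambda_: float | None = None,
    vc: VarianceComponents | None = None,
) -> ModelFit:
    """Genomic BLUP of genetic values from the GRM.

    u_hat = G sigma2_u V^{-1} (y - 1 mu_hat) with V = G sigma2_u + I sigma2_e
    and a GLS intercept; equivalently u_hat = G (G + delta I)^{-1} (y - mu).
    """
    y = np.asarray(y, dtype=float)
    A = _as_matrix(G)
    n = y.size
    eigvals = np.linalg.eigvalsh(A)
    if eigvals.min() < -1e-6 * max(1.0, abs(eigvals.max())):
        raise ValueError("G is not positive semidefinite")
    if lambda_ is None:
        vc = vc or estimate_variance_components(y, A)
        lambda_ = vc.ratio
    if lambda_ < 0:
        raise ValueError("lambda must be nonnegative")

    if np.isinf(lambda_):
        mu = float(y.mean())
        u = np.zeros(n)
        Vinv_r = np.zeros(n)
    else:
        H = A + lambda_ * np.eye(n)
        jit = 0.0
        while True:
            try:
                Hinv = np.linalg.inv(H + jit * np.eye(n))
                break
            except np.linalg.LinAlgError:
                jit = 1e-8 if jit == 0 else jit * 10
                if jit > 1.0:
                    raise
        ones = np.ones(n)
        mu = float(ones @ Hinv @ y / (ones @ Hinv @ ones))
        Vinv_r = Hinv @ (y - mu)  # (G + delta I)^{-1} residual
        u = A @ Vinv_r
    return ModelFit(
        model="gBLUP",
        gebv=u,
        intercept=mu,
        residuals=y - mu - u,
        vc=vc,
        regularization={"lambda": float(lambda_)},
        state={"alpha": Vinv_r},  # cross-kinship rows @ alpha predicts new GEBVs
    )


def fit_rkhs(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    lambda_: float | None = None,
    vc: VarianceComponents | None = None,
) -> ModelFit:
    """Kernel ridge regression in the RKHS of a (Gaussian) kernel.

    alpha_hat = (K + lambda I)^{-1} (y - 1 mu_hat), GEBV = K alpha_hat;
    lambda from REML on K (RKHS/gBLUP duality) when not supplied.
    """
    y = np.asarray(y, dtype=float)
    A = _as_matrix(K)
    n = y.size
    if lambda_ is None:
        vc = vc or estimate_variance_components(y, A)
        lambda_ = vc.ratio
    if np.isinf(lambda_):
        mu, alpha = float(y.mean()), np.zeros(n)
    else:
        H = A + lambda_ * np.eye(n)
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"singular (K + lambda I): {err}") from err
        ones = np.ones(n)
        mu = float(ones @ Hinv @ y / (ones @ Hinv @ ones))
        alpha = Hinv @ (y - mu)
    gebv = A @ alpha
    return ModelFit(
        model="RKHS",
        gebv=gebv,
        intercept=mu,
        residuals=y - mu - gebv,
        vc=vc,
        regularization={"lambda": float(lambda_)},
        state={"alpha": alpha},
    )


# ---------------------------------------------------------------------------
# Penalized and Bayesian marker regressions
# ---------------------------------------------------------------------------


def fit_lasso(
    y: np.ndarray,
    X: np.ndarray,
    lambda_: float | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    max_iter: int = 50000,
) -> ModelFit:
    """L1-penalized marker regression (cyclic coordinate descent).

    Minimizes (1/2n)||y - mu - X b||^2 + lambda ||b||_1; lambda picked on a
    log grid by inner cross-validation when not supplied.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    meta: dict = {}
    if lambda_ is None:
        cv = LassoCV(
            alphas=30, cv=cv_folds, random_state=seed, max_iter=max_iter
        ).fit(X, y)
        lambda_ = float(cv.alpha_)
        mu, beta = float(cv.intercept_), cv.coef_.copy()
        n_it = int(np.max(cv.n_iter_))
    else:
        est = Lasso(alpha=lambda_, max_iter=max_iter, tol=1e-8).fit(X, y)
        mu, beta = float(est.intercept_), est.coef_.copy()
        n_it = int(est.n_iter_)
        if n_it >= max_iter:
            raise RuntimeError(
                f"LASSO coordinate descent did not converge in {max_iter} sweeps "
                f"(lambda={lambda_})"
            )
    meta["n_iter"] = n_it
    gebv = X @ beta
    return ModelFit(
        model="LASSO",
        gebv=gebv,
        intercept=mu,
        residuals=y - mu - gebv,
        marker_effects=beta,
        regularization={"lambda": float(lambda_)},
        training_meta=meta,
    )


def fit_bayesian_ridge(
    y: np.ndarray,
    X: np.ndarray,
    n_iter: int = 2000,
    burn_in: int = 500,
    seed: int = 0,
    fixed_variances: tuple[float, float] | None = None,
    prior_df: float = 4.0,
    prior_scale: float | None = None,
    n_kept_draws: int = 200,
) -> ModelFit:
    """Gibbs sampler for the Bayesian ridge marker model (BGLR-type).

    y = 1 mu + X alpha + e with alpha_j ~ N(0, sigma2_alpha) and scaled
    inverse-chi-square priors on both variances.  The sampler runs in the
    SVD-rotated coordinate system where the conditional posterior of the
    rotated effects is diagonal, so each sweep costs O(rank) — an exact
    reparameterization of the naive p-dimensional sampler.  Marker-effect
    summaries (posterior mean and sign probability) are recovered by
    rotating thinned draws back.

    ``fixed_variances=(sigma2_alpha, sigma2_e)`` freezes the variances and
    the intercept at zero, giving draws from the conjugate ridge posterior.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    r = int(np.sum(s > s.max() * 1e-12)) if s.size else 0
    U, s, Vt = U[:, :r], s[:r], Vt[:r]
    Uty = U.T @ y
    Ut1 = U.T @ np.ones(n)

    fixed = fixed_variances is not None
    if fixed:
        s2a, s2e = map(float, fixed_variances)
        mu = 0.0
    else:
        s2e = float(y.var()) or 1.0
        s2a = s2e / max(p, 1)
        mu = float(y.mean())
    if prior_scale is None:
        prior_scale = max(float(y.var()), 1e-8) / max(p, 1)
    nu0, se0 = prior_df, max(float(y.var()), 1e-8)

    a = np.zeros(r)  # rotated effects V' alpha along the row space
    keep_every = max((n_iter - burn_in) // n_kept_draws, 1)
    a_draws, s2a_draws, s2e_draws, mu_draws = [], [], [], []
    a_sum = np.zeros(r)
    mu_sum = 0.0
    n_kept = 0

    for it in range(n_iter):
        # rotated effects: independent normal conditionals
        prec = s**2 / s2e + 1.0 / s2a
        mean = (s * (Uty - mu * Ut1)) / s2e / prec
        a = mean + rng.standard_normal(r) / np.sqrt(prec)
        if not np.isfinite(a).all():
            raise FloatingPointError("divergent chain: non-finite effect draws")

        if not fixed:
            # null-space effect mass enters only the sigma2_alpha update
            null_ss = s2a * rng.chisquare(p - r) if p > r else 0.0
            ss_alpha = float(a @ a) + null_ss
            s2a = (nu0 * prior_scale + ss_alpha) / rng.chisquare(nu0 + p)
            resid = y - mu - U @ (s * a)
            s2e = (nu0 * se0 + float(resid @ resid)) / rng.chisquare(nu0 + n)
            resid_mu = y - U @ (s * a)
            mu = float(rng.normal(resid_mu.mean(), np.sqrt(s2e / n)))

        if it >= burn_in:
            a_sum += a
            mu_sum += mu
            n_kept += 1
            if (it - burn_in) % keep_every == 0:
                a_draws.append(a.copy())
                s2a_draws.append(s2a)
                s2e_draws.append(s2e)
                mu_draws.append(mu)

    a_bar = a_sum / n_kept
    alpha_bar = Vt.T @ a_bar
    mu_bar = mu_sum / n_kept
    gebv = U @ (s * a_bar)

    # posterior sign probability per marker from thinned rotated draws; the
    # null-space component is sign-symmetric and pulls these toward 0.5,
    # which the row-space summary deliberately excludes
    A_draws = np.array(a_draws)
    alpha_draws = A_draws @ Vt
    sign_prob = (alpha_draws > 0).mean(axis=0)

    s2a_post = float(np.mean(s2a_draws))
    s2e_post = float(np.mean(s2e_draws))
    vc = VarianceComponents(sigma2_a=max(s2a_post * p, 0.0), sigma2_e=s2e_post)
    return ModelFit(
        model="BGLR",
        gebv=gebv,
        intercept=mu_bar,
        residuals=y - mu_bar - gebv,
        marker_effects=alpha_bar,
        vc=vc,
        regularization={"lambda": s2e_post / s2a_post if s2a_post > 0 else np.inf},
        training_meta={
            "n_iter": n_iter,
            "burn_in": burn_in,
            "seed": seed,
            "sign_prob": sign_prob,
            "n_kept_draws": len(a_draws),
        },
    )


# ---------------------------------------------------------------------------
# Kernel SVR and tree ensembles
# ---------------------------------------------------------------------------


def fit_svr(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    epsilon: float = 0.1,
    C: float = 1.0,
) -> ModelFit:
    """Epsilon-insensitive support-vector regression on a precomputed kernel.

    Solved in the dual (SMO box-constrained coordinate ascent).  When the
    epsilon tube covers the whole response range the bias is non-unique; the
    midrange of y is returned (deterministic tie rule).
    """
    y = np.asarray(y, dtype=float)
    A = _as_matrix(K)
    if epsilon < 0 or C <= 0:
        raise ValueError("need epsilon >= 0 and C > 0")
    est = SVR(kernel="precomputed", C=C, epsilon=epsilon, tol=1e-6, max_iter=200000)
    est.fit(A, y)
    if est.fit_status_ != 0:
        raise RuntimeError("SVR solver did not converge within the iteration cap")
    n = y.size
    dual = np.zeros(n)
    dual[est.support_] = est.dual_coef_.ravel()
    n_sv = int(est.support_.size)
    if n_sv == 0:
        bias = float((y.max() + y.min()) / 2.0)
    else:
        bias = float(est.intercept_[0])
    gebv = A @ dual
    return ModelFit(
        model="SVM",
        gebv=gebv,
        intercept=bias,
        residuals=y - bias - gebv,
        regularization={"epsilon": float(epsilon), "C": float(C)},
        training_meta={"n_support_vectors": n_sv},
        state={"alpha": dual},
    )


def svr_dual_objective(
    K: np.ndarray, y: np.ndarray, dual: np.ndarray, epsilon: float
) -> float:
    """Dual objective at a feasible point with alpha_i * alpha*_i = 0,
    parameterized by the signed coefficients beta = alpha - alpha*."""
    return float(
        -0.5 * dual @ K @ dual - epsilon * np.abs(dual).sum() + y @ dual
    )


def fit_boosting(
    y: np.ndarray,
    X: np.ndarray,
    learning_rate: float = 0.1,
    n_rounds: int = 100,
    max_depth: int = 2,
    schedule: np.ndarray | None = None,
    seed: int = 0,
) -> ModelFit:
    """Stage-wise gradient boosting under squared loss, F0 = 0.

    Weak learners are depth-limited regression trees on the marker columns
    (``max_depth=0`` gives the constant mean learner).  A per-round learning
    rate ``schedule`` overrides the constant rate when supplied; the rate
    trace is recorded either way.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (0.0 <= learning_rate <= 1.0):
        raise ValueError("learning_rate must lie in [0, 1]")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if schedule is not None and len(schedule) < n_rounds:
        raise ValueError("schedule shorter than n_rounds")

    F = np.zeros_like(y)
    trees: list = []
    rates, mse_trace = [], []
    for mround in range(n_rounds):
        v = float(schedule[mround]) if schedule is not None else learning_rate
        resid = y - F
        if max_depth == 0:
            pred = np.full_like(y, resid.mean())
            trees.append(("const", float(resid.mean())))
        else:
            tree = DecisionTreeRegressor(max_depth=max_depth, random_state=seed + mround)
            tree.fit(X, resid)
            pred = tree.predict(X)
            trees.append(("tree", tree))
        F = F + v * pred
        rates.append(v)
        mse_trace.append(float(np.mean((y - F) ** 2)))
    return ModelFit(
        model="BOOST",
        gebv=F,
        intercept=0.0,
        residuals=y - F,
        regularization={"learning_rate": float(learning_rate), "max_depth": max_depth},
        training_meta={
            "n_rounds": n_rounds,
            "learning_rate_trace": np.array(rates),
            "train_mse_trace": np.array(mse_trace),
            "seed": seed,
        },
        state={"trees": trees, "rates": rates},
    )


def fit_bagging(
    y: np.ndarray,
    X: np.ndarray,
    n_bags: int = 50,
    max_depth: int | None = None,
    seed: int = 0,
) -> ModelFit:
    """Bootstrap-aggregated regression trees.

    GEBV is the across-bag mean prediction; out-of-bag MSE and the
    bootstrap mean of resampled responses (the ensemble-bias estimate) are
    reported.  ``max_depth=0`` forces the constant mean base learner.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    rng = np.random.default_rng(seed)
    n = y.size
    preds = np.zeros((n_bags, n))
    in_bag = np.zeros((n_bags, n), dtype=bool)
    trees: list = []
    boot_means = []
    for b in range(n_bags):
        idx = rng.integers(0, n, size=n)
        in_bag[b, np.unique(idx)] = True
        boot_means.append(float(y[idx].mean()))
        if max_depth == 0:
            trees.append(("const", float(y[idx].mean())))
            preds[b] = y[idx].mean()
        else:
            tree = DecisionTreeRegressor(
                max_depth=max_depth, random_state=int(rng.integers(2**31 - 1))
            )
            tree.fit(X[idx], y[idx])
            trees.append(("tree", tree))
            preds[b] = tree.predict(X)
    gebv = preds.mean(axis=0)
    oob_mask = ~in_bag
    with np.errstate(invalid="ignore"):
        oob_pred = np.where(
            oob_mask.any(axis=0),
            np.nansum(np.where(oob_mask, preds, np.nan), axis=0)
            / np.maximum(oob_mask.sum(axis=0), 1),
            np.nan,
        )
    has_oob = oob_mask.any(axis=0)
    oob_mse = float(np.mean((y[has_oob] - oob_pred[has_oob]) ** 2)) if has_oob.any() else np.nan
    return ModelFit(
        model="BAGG",
        gebv=gebv,
        intercept=0.0,
        residuals=y - gebv,
        regularization={"n_bags": n_bags, "max_depth": max_depth},
        training_meta={
            "oob_mse": oob_mse,
            "bootstrap_mean": float(np.mean(boot_means)),
            "seed": seed,
        },
        state={"trees": trees},
    )


def fit_stacking(
    oof_predictions: np.ndarray,
    y: np.ndarray,
    base_names: list[str],
    base_gebvs: np.ndarray | None = None,
    epsilon: float = 0.0,
    nonneg: bool = True,
) -> ModelFit:
    """Stacked ensemble: non-negative least squares over out-of-fold base
    predictions plus a free intercept.

    ``oof_predictions`` is n x n_bases; ``base_gebvs`` (same layout, final
    refit predictions) composes the reported training GEBV when given.  The
    epsilon-insensitive meta loss sum(max(|r| - eps, 0)) is reported; with
    all residuals inside the tube it is exactly zero.
    """
    P = np.asarray(oof_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    n, n_base = P.shape
    if n_base < 2:
        raise ValueError("stacking needs at least 2 base models")
    if len(base_names) != n_base:
        raise ValueError("base_names length mismatch")

    A = np.column_stack([np.ones(n), P])
    lb = np.concatenate(([-np.inf], np.zeros(n_base) if nonneg else -np.inf * np.ones(n_base)))
    ub = np.full(n_base + 1, np.inf)
    sol = lsq_linear(A, y, bounds=(lb, ub))
    intercept, w = float(sol.x[0]), sol.x[1:]

    combined_src = P if base_gebvs is None else np.asarray(base_gebvs, dtype=float)
    gebv = combined_src @ w
    resid = y - intercept - P @ w
    meta_loss = float(np.maximum(np.abs(resid) - epsilon, 0.0).sum())
    return ModelFit(
        model="STACK",
        gebv=gebv,
        intercept=intercept,
        residuals=y - intercept - gebv,
        regularization={"epsilon": float(epsilon)},
        training_meta={
            "weights": dict(zip(base_names, w.tolist())),
            "meta_loss_eps": meta_loss,
        },
        state={"weights": w, "base_names": list(base_names)},
    )


def serialize_fit(fit: ModelFit, out_dir) -> None:
    """Write a fitted model as text artifacts: scalars and weights to
    ``<model>.json``, GEBVs (and marker effects when defined) to TSV."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "model": fit.model,
        "intercept": fit.intercept,
        "regularization": {k: float(v) for k, v in fit.regularization.items()},
        "vc": None
        if fit.vc is None
        else {"sigma2_a": fit.vc.sigma2_a, "sigma2_e": fit.vc.sigma2_e, "h2": fit.vc.h2},
        "training_meta": {
            k: v for k, v in fit.training_meta.items()
            if isinstance(v, (int, float, str, dict))
        },
    }
    with open(out / f"{fit.model}.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    import pandas as pd

    pd.DataFrame({"gebv": fit.gebv, "residual": fit.residuals}).to_csv(
        out / f"{fit.model}_gebv.tsv", sep="\t", index_label="idx",
        float_format="%.10g",
    )
    if fit.marker_effects is not None:
        pd.DataFrame({"effect": fit.marker_effects}).to_csv(
            out / f"{fit.model}_effects.tsv", sep="\t", index_label="marker_idx",
            float_format="%.10g",
        )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict(fit: ModelFit, new: np.ndarray) -> np.ndarray:
    """GEBVs for new genotypes.

    ``new`` is coded marker rows for marker/tree models (rrBLUP, LASSO, BGLR,
    BOOST, BAGG), kernel/GRM rows against the training set for gBLUP, RKHS
    and SVM, and a matrix of base-model predictions for STACK.
    """
    new = np.asarray(new, dtype=float)
    if fit.model in ("rrBLUP", "LASSO", "BGLR"):
        if new.shape[1] != fit.marker_effects.size:
            raise ValueError(
                f"marker mismatch: fit has {fit.marker_effects.size} markers, "
                f"input has {new.shape[1]}"
            )
        return new @ fit.marker_effects
    if fit.model in ("gBLUP", "RKHS", "SVM"):
        alpha = fit.state["alpha"]
        if new.shape[1] != alpha.size:
            raise ValueError(
                f"kernel-row mismatch: fit has {alpha.size} training genotypes, "
                f"input rows have {new.shape[1]}"
            )
        return new @ alpha
    if fit.model == "BOOST":
        F = np.zeros(new.shape[0])
        for v, (kind, t) in zip(fit.state["rates"], fit.state["trees"]):
            F += v * (t if kind == "const" else t.predict(new))
        return F
    if fit.model == "BAGG":
        preds = [
            (np.full(new.shape[0], t) if kind == "const" else t.predict(new))
            for kind, t in fit.state["trees"]
        ]
        return np.mean(preds, axis=0)
    if fit.model == "STACK":
        w = fit.state["weights"]
        if new.shape[1] != w.size:
            raise ValueError(
                f"base-prediction mismatch: fit combines {w.size} bases, "
                f"input has {new.shape[1]} columns"
            )
        return new @ w
    raise ValueError(f"unknown model {fit.model!r}")
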