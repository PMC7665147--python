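"""Scalar-on-function regression with a decomposition-based penalty.

Model: for subject i with scalar covariates x_i (intercept, male indicator,
cadence, VMC) and order-domain walking spectrum W_i(.),

    y_i = x_i' gamma + int W_i(s) beta(s) ds + eps_i,   eps_i ~ N(0, sigma_eps^2).

On the p-point order grid the integral becomes delta_s * sum_j w_i(s_j)
beta(s_j), so in matrix form y = X gamma + W beta + eps with W carrying the
quadrature weight.  The penalized criterion

    ||y - X gamma - W beta||^2 + lambda ||L beta||^2

is minimized in closed form by the generalized ridge solution; lambda is the
variance ratio sigma_eps^2 / sigma_beta^2 of the equivalent linear mixed
model (b = L beta random, iid Gaussian), estimated by REML.  Pointwise
confidence bands for beta come from the mixed-model (Bayesian/ridge)
covariance of the penalized estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, JoinError, ParameterError, RankError, StructuralError
from .penalty import PenaltyOperator
from .preprocess import SubjectFeatures

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSet",
    "FunctionalFit",
    "assemble_design",
    "fit_generalized_ridge",
    "select_lambda_reml",
    "confidence_bands",
    "significant_multiples",
    "fit_functional_model",
]

LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass
class DesignSet:
    """Aligned response, scalar design, and spectrum matrix for one cohort."""

    y: np.ndarray                 # (N,)
    X: np.ndarray                 # (N, K) scalar predictors, first column = 1
    W: np.ndarray                 # (N, p) spectra, pre-multiplied by delta_s
    order_grid: np.ndarray        # (p,)
    delta_s: float
    x_names: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.W.shape[1]


@dataclass
class FunctionalFit:
    """Penalized fit: scalar coefficients, coefficient function, and bands."""

    gamma_hat: np.ndarray
    beta_hat: np.ndarray
    lam: float
    sigma_eps2: float
    sigma_beta2: float
    cov_coef: np.ndarray          # joint (K+p) covariance of (gamma, beta)
    band_lower: np.ndarray
    band_upper: np.ndarray
    order_grid: np.ndarray
    x_names: list[str] = field(default_factory=list)
    gamma_se: np.ndarray | None = None
    level: float = 0.95

    def scalar_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.x_names, "estimate": self.gamma_hat, "se": self.gamma_se}
        )


def assemble_design(
    features: list[SubjectFeatures],
    covariates: pd.DataFrame,
    response: str = "y",
    scale_by_delta: bool = True,
    drop_constant: bool = True,
) -> DesignSet:
    """Join spectra with scalar covariates into aligned design blocks.

    ``covariates`` must carry ``subject_id``, ``male`` and the response
    column; cadence and VMC come from the features.  The spectrum matrix is
    multiplied by the grid spacing delta_s so that W beta is the Riemann-sum
    quadrature of the integral term (disable with ``scale_by_delta``).
    Constant scalar columns other than the intercept are dropped with a
    warning rather than producing a singular design.
    """
    if not features:
        raise StructuralError("no subject features supplied")
    cov = covariates.set_index(covariates["subject_id"].astype(str))
    ids = [str(f.subject_id) for f in features]
    missing = [i for i in ids if i not in cov.index]
    if missing:
        raise JoinError(f"no covariate row for subject(s): {missing}")
    if response not in cov.columns:
        raise JoinError(f"response column {response!r} not in covariate table")
    cov = cov.loc[ids]
    if cov[response].isna().any():
        bad = cov.index[cov[response].isna()].tolist()
        raise JoinError(f"missing response for subject(s): {bad}")

    grid = features[0].order_grid
    delta_s = float(grid[1] - grid[0])
    W = np.vstack([f.spectrum for f in features])
    if scale_by_delta:
        W = W * delta_s

    cols = {
        "intercept": np.ones(len(ids)),
        "male": cov["male"].to_numpy(dtype=float),
        "cadence": np.array([f.cadence_hz for f in features]),
        "vmc": np.array([f.vmc for f in features]),
    }
    names, arrays = [], []
    for name, col in cols.items():
        if drop_constant and name != "intercept" and np.ptp(col) == 0.0:
            logger.warning("dropping constant scalar predictor %r", name)
            continue
        names.append(name)
        arrays.append(col)
    X = np.column_stack(arrays)
    y = cov[response].to_numpy(dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(W).all() and np.isfinite(y).all()):
        raise StructuralError("non-finite values in assembled design")
    return DesignSet(
        y=y, X=X, W=W, order_grid=np.asarray(grid, float),
        delta_s=delta_s, x_names=names, subject_ids=ids,
    )


def _penalized_system(ds: DesignSet, Lop: PenaltyOperator, lam: float):
    """Normal-equation matrix Xo'Xo + lam * blockdiag(0, L'L) and Xo'y."""
    Xo = np.hstack([ds.X, ds.W])
    K = ds.X.shape[1]
    A = Xo.T @ Xo
    A[K:, K:] += lam * Lop.LtL
    return A, Xo.T @ ds.y, K


def fit_generalized_ridge(
    ds: DesignSet, Lop: PenaltyOperator, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form minimizer of the penalized least-squares criterion.

    Only the functional block beta is penalized; lam = 0 requires the
    unpenalized normal equations to be invertible (fails for p > N).
    """
    if lam < 0:
        raise ParameterError("lambda must be nonnegative")
    if not (np.isfinite(ds.y).all() and np.isfinite(ds.X).all() and np.isfinite(ds.W).all()):
        raise StructuralError("non-finite values in design")
    A, b, K = _penalized_system(ds, Lop, lam)
    if lam == 0 and ds.p + K > ds.n:
        raise RankError(f"lambda = 0 with p + K = {ds.p + K} > N = {ds.n}: singular system")
    try:
        coef = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise RankError(f"singular penalized system at lambda = {lam}") from exc
    return coef[:K], coef[K:]


def select_lambda_reml(
    ds: DesignSet,
    Lop: PenaltyOperator,
    bounds: tuple[float, float] = LAMBDA_BOUNDS,
) -> tuple[float, float, float]:
    """REML selection of the penalty weight via the mixed-model equivalence.

    Substituting b = L beta turns the criterion into the mixed model
    y = X gamma + Z b + eps with Z = W L^{-1}, b ~ N(0, sigma_beta^2 I),
    eps ~ N(0, sigma_eps^2 I), so lambda = sigma_eps^2 / sigma_beta^2.  The
    restricted log-likelihood is profiled over log lambda with a bounded 1-D
    optimizer; an eigendecomposition of Z Z' makes each evaluation O(N^2).

    Returns (lambda, sigma_eps^2, sigma_beta^2).  When the data carry no
    functional signal the optimum sits at the upper bound (beta shrunk to
    ~0); this is reported with a warning rather than an error.
    """
    N, K = ds.n, ds.X.shape[1]
    if N <= K:
        raise ParameterError("need more subjects than scalar predictors for REML")
    Z = ds.W @ Lop.L_inv
    d, U = np.linalg.eigh(Z @ Z.T)            # V = sigma_eps^2 (I + ZZ'/lam)
    d = np.clip(d, 0.0, None)
    Uy = U.T @ ds.y
    UX = U.T @ ds.X

    def _gls(lam: float):
        w = 1.0 / (1.0 + d / lam)             # eigenvalues of H^{-1}
        M = (UX * w[:, None]).T @ UX          # X' H^{-1} X
        v = (UX * w[:, None]).T @ Uy          # X' H^{-1} y
        try:
            gamma = np.linalg.solve(M, v)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular GLS system in REML profile") from exc
        # residual quadratic form computed as a sum of squares: the
        # difference form y'H^{-1}y - v'M^{-1}v cancels catastrophically
        # for small lambda and can go (falsely) negative
        r = Uy - UX @ gamma
        q = float(r @ (w * r))
        return gamma, M, q

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        _, M, q = _gls(lam)
        q = max(q, 1e-300)
        sign, logdet_M = np.linalg.slogdet(M)
        if sign <= 0:
            raise ConvergenceError("non-PD X'H^{-1}X in REML profile")
        return (N - K) * np.log(q) + float(np.sum(np.log1p(d / lam))) + logdet_M

    # the restricted-likelihood profile can be multimodal in lambda (a local
    # optimum at heavy shrinkage coexists with the signal optimum), so scan a
    # coarse log grid first and refine around the best point
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    grid_ll = np.linspace(lo, hi, 49)
    values = np.array([neg2_reml(ll) for ll in grid_ll])
    j = int(np.argmin(values))
    b_lo = grid_ll[max(j - 1, 0)]
    b_hi = grid_ll[min(j + 1, len(grid_ll) - 1)]
    res = optimize.minimize_scalar(neg2_reml, bounds=(b_lo, b_hi), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise ConvergenceError(f"REML profile optimization failed: {res.message}")
    lam = float(np.exp(res.x))
    if values[j] < res.fun:
        lam = float(np.exp(grid_ll[j]))
    if lam >= bounds[1] * 0.99:
        logger.warning("REML lambda capped at %.3g: no evidence of functional signal", bounds[1])
        lam = bounds[1]

    _, _, q = _gls(lam)
    sigma_eps2 = max(q, 0.0) / (N - K)
    sigma_beta2 = sigma_eps2 / lam
    return lam, sigma_eps2, sigma_beta2


def confidence_bands(
    ds: DesignSet,
    Lop: PenaltyOperator,
    lam: float,
    sigma_eps2: float,
    level: float = 0.95,
    method: str = "ridge",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise confidence bands for the coefficient function.

    ``method='ridge'`` uses the mixed-model (Bayesian) covariance
    sigma_eps^2 (Xo'Xo + lam Lo'Lo)^{-1}, the standard choice for penalized
    regression bands; ``method='sandwich'`` uses the frequentist form
    sigma_eps^2 A^{-1} Xo'Xo A^{-1}.  The selected lambda is plugged in; its
    sampling variability is ignored.

    Returns (gamma_hat, beta_hat, cov_coef, band_lower, band_upper).
    """
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    A, b, K = _penalized_system(ds, Lop, lam)
    Ainv = np.linalg.inv(A)
    coef = Ainv @ b
    if method == "ridge":
        cov = sigma_eps2 * Ainv
    elif method == "sandwich":
        Xo = np.hstack([ds.X, ds.W])
        cov = sigma_eps2 * Ainv @ (Xo.T @ Xo) @ Ainv
    else:
        raise ParameterError(f"unknown band method {method!r}")
    cov = (cov + cov.T) / 2.0
    var = np.diag(cov)
    if var.min() < -1e-10 * max(var.max(), 1.0):
        raise ConvergenceError("covariance not PSD after symmetrization")
    se = np.sqrt(np.clip(var, 0.0, None))
    z = stats.norm.ppf(0.5 + level / 2.0)
    beta = coef[K:]
    se_beta = se[K:]
    return coef[:K], beta, cov, beta - z * se_beta, beta + z * se_beta


def significant_multiples(
    fit: FunctionalFit, centers: np.ndarray | list[float]
) -> list[float]:
    """Basis-center multiples where the pointwise band excludes zero.

    Each center is evaluated at the nearest order-grid point.
    """
    out = []
    for c in np.asarray(centers, dtype=float):
        j = int(np.argmin(np.abs(fit.order_grid - c)))
        if fit.band_lower[j] > 0.0 or fit.band_upper[j] < 0.0:
            out.append(float(c))
    return out


def fit_functional_model(
    ds: DesignSet,
    Lop: PenaltyOperator,
    lam: float | None = None,
    level: float = 0.95,
    band_method: str = "ridge",
) -> FunctionalFit:
    """REML-tuned generalized ridge fit with pointwise bands.

    If ``lam`` is given it is used as-is and sigma_eps^2 is estimated from
    the penalized residuals via the effective degrees of freedom.
    """
    if lam is None:
        lam, sigma_eps2, sigma_beta2 = select_lambda_reml(ds, Lop)
    else:
        gamma, beta = fit_generalized_ridge(ds, Lop, lam)
        resid = ds.y - ds.X @ gamma - ds.W @ beta
        A, _, K = _penalized_system(ds, Lop, lam)
        Xo = np.hstack([ds.X, ds.W])
        edf = float(np.trace(np.linalg.solve(A, Xo.T @ Xo)))
        dof = max(ds.n - edf, 1.0)
        sigma_eps2 = float(resid @ resid) / dof
        sigma_beta2 = sigma_eps2 / lam if lam > 0 else np.inf
    gamma, beta, cov, lower, upper = confidence_bands(
        ds, Lop, lam, sigma_eps2, level=level, method=band_method
    )
    K = ds.X.shape[1]
    gamma_se = np.sqrt(np.clip(np.diag(cov)[:K], 0.0, None))
    return FunctionalFit(
        gamma_hat=gamma,
        beta_hat=beta,
        lam=float(lam),
        sigma_eps2=float(sigma_eps2),
        sigma_beta2=float(sigma_beta2),
        cov_coef=cov,
        band_lower=lower,
        band_upper=upper,
        order_grid=ds.order_grid,
        x_names=list(ds.x_names),
        gamma_se=gamma_se,
        level=level,
    )
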