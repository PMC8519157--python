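"""Function-on-scalar regression (FOSR) with penalized GLS estimation.

The model regresses a functional outcome — each subject's mean (or SD)
rest/activity profile over the 24-h grid — on scalar covariates:

    Y_i(t) = beta_0(t) + age_i*beta_1(t) + sex_i*beta_2(t)
             + education_i*beta_3(t) + group_i*beta_4(t) + e_i(t)

Each coefficient function is expanded in a spline basis, beta_j(t) =
B(t)' theta_j (eight cubic B-splines by default), estimated by penalized
least squares with a difference penalty on the basis coefficients, the
smoothing parameter chosen by generalized cross-validation (GCV). A second
pass re-estimates by penalized *generalized* least squares, weighting by the
inverse of the residual covariance over the grid estimated from the first
pass. Inference offers per-point (pointwise) confidence bands, simultaneous
bands via the parametric max-statistic construction, and a permutation global
F-test for each covariate.

The default basis is non-periodic: the fit does not tie together the two ends
of the 24-h day, which loses a little power around midnight; ``periodic=True``
wraps the basis as a remedy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline
from scipy.stats import norm

from .preprocessing import SubjectRAR
from .utils import hours_to_clock

__all__ = [
    "FunctionalDesign",
    "FOSRFit",
    "Band",
    "Window",
    "build_basis",
    "build_design",
    "fit_fosr",
    "pointwise_band",
    "simultaneous_band",
    "global_f_test",
    "significant_windows",
]

DEFAULT_COLUMNS = ("intercept", "age", "sex", "education", "abeta")


# --------------------------------------------------------------------------- basis


def build_basis(
    grid,
    n_basis: int,
    periodic: bool = False,
    family: str = "bspline",
    period: float = 24.0,
    penalty_order: int = 2,
):
    """Basis matrix (len(grid) x n_basis) and matching roughness penalty.

    ``family="bspline"``: cubic B-splines with evenly spaced knots on
    [0, period], clamped at the ends (non-periodic) or cardinal and wrapped
    (periodic). ``family="fourier"``: intercept plus sine/cosine pairs.
    The penalty is the ``penalty_order``-th difference penalty D'D on the
    basis coefficients (circular differences when periodic); for Fourier it is
    the diagonal curvature penalty.
    """
    grid = np.asarray(grid, dtype=float)
    if family == "fourier":
        if n_basis % 2 == 0:
            raise ValueError("fourier basis needs odd n_basis (1 + sin/cos pairs)")
        w = 2.0 * np.pi / period
        cols = [np.ones_like(grid)]
        pen = [0.0]
        for k in range(1, (n_basis - 1) // 2 + 1):
            cols += [np.cos(k * w * grid), np.sin(k * w * grid)]
            pen += [(k * w) ** 4] * 2
        return np.column_stack(cols), np.diag(pen)

    if family != "bspline":
        raise ValueError(f"unknown basis family {family!r}")
    if n_basis < 4:
        raise ValueError("cubic B-splines require n_basis >= 4")

    if periodic:
        # cardinal cubic B-splines at K evenly spaced centers, evaluated on
        # the circle: partition of unity, translation invariant
        h = period / n_basis
        centers = np.arange(n_basis) * h
        b = BSpline.basis_element(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]), extrapolate=False)
        d = grid[:, None] - centers[None, :]
        d = (d + period / 2.0) % period - period / 2.0  # wrap to [-P/2, P/2)
        u = d / h
        B = np.where(np.abs(u) < 2.0, np.nan_to_num(b(np.clip(u, -2, 2))), 0.0)
        idx = np.arange(n_basis)
        D = (
            np.eye(n_basis)[(idx) % n_basis]
            - 2 * np.eye(n_basis)[(idx + 1) % n_basis]
            + np.eye(n_basis)[(idx + 2) % n_basis]
        )
        if penalty_order == 1:
            D = np.eye(n_basis)[idx % n_basis] - np.eye(n_basis)[(idx + 1) % n_basis]
        return B, D.T @ D

    n_interior = n_basis - 4
    knots = np.concatenate(
        [np.zeros(3), np.linspace(0.0, period, n_interior + 2), np.full(3, period)]
    )
    B = BSpline.design_matrix(grid, knots, 3).toarray()
    D = np.diff(np.eye(n_basis), n=penalty_order, axis=0)
    return B, D.T @ D


# --------------------------------------------------------------------------- design


@dataclass
class FunctionalDesign:
    """Aligned outcome matrix, design matrix, and evaluation grid."""

    Y: np.ndarray  # (n_subjects, n_bins)
    X: np.ndarray  # (n_subjects, q); first column = intercept
    grid: np.ndarray  # bin midpoint clock hours
    col_names: tuple[str, ...] = DEFAULT_COLUMNS
    n_basis: int = 8
    periodic: bool = False
    family: str = "bspline"

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        n, T = self.Y.shape
        if self.X.shape[0] != n:
            raise ValueError("Y and X must have aligned rows")
        if len(self.col_names) != self.X.shape[1]:
            raise ValueError("col_names must match X columns")
        if np.isnan(self.Y).any():
            raise ValueError("Y must be complete (drop excluded subjects upstream)")
        if self.X.shape[1] >= n:
            raise ValueError("need more subjects than covariates")
        if T >= n:
            warnings.warn(
                f"n_bins={T} >= n_subjects={n}: residual covariance estimation "
                "is unstable at this resolution",
                stacklevel=2,
            )

    def column(self, j) -> int:
        if isinstance(j, str):
            return self.col_names.index(j)
        return int(j)


def build_design(
    rars: list[SubjectRAR],
    covariates: pd.DataFrame,
    outcome: str = "mean",
    n_basis: int = 8,
    periodic: bool = False,
    center: bool = True,
) -> FunctionalDesign:
    """Assemble Y and X from subject profiles and the covariate table.

    ``outcome`` selects the mean or SD profile. Sex is coded 1=female, amyloid
    status 1=positive; all non-intercept columns are mean-centered by default,
    so the intercept function estimates the sample-average profile and
    ``beta_4`` the adjusted positive-minus-negative contrast.
    """
    cov = covariates.set_index("subject_id")
    rows, Y = [], []
    for r in rars:
        if r.subject_id not in cov.index:
            raise KeyError(f"{r.subject_id} missing from covariate table")
        c = cov.loc[r.subject_id]
        rows.append(
            [
                1.0,
                float(c["age"]),
                1.0 if c["sex"] == "F" else 0.0,
                float(c["education_years"]),
                1.0 if c["abeta"] == "pos" else 0.0,
            ]
        )
        Y.append(r.mean_profile if outcome == "mean" else r.sd_profile)
    X = np.asarray(rows)
    if center:
        X[:, 1:] -= X[:, 1:].mean(axis=0)
    grid = rars[0].bin_midpoints_hours
    return FunctionalDesign(
        Y=np.asarray(Y), X=X, grid=grid, n_basis=n_basis, periodic=periodic
    )


# --------------------------------------------------------------------------- fit


@dataclass
class FOSRFit:
    design: FunctionalDesign
    B: np.ndarray  # (T, K) basis on the grid
    P: np.ndarray  # (K, K) penalty
    theta: np.ndarray  # (q, K) basis coefficients
    coef: np.ndarray  # (q, T) coefficient functions on the grid
    se: np.ndarray  # (q, T) pointwise standard errors
    cov_theta: np.ndarray  # (qK, qK) covariance of vec coefficients
    Sigma: np.ndarray  # (T, T) residual covariance estimate
    W: np.ndarray  # (T, T) GLS weight used for the final fit
    lambda_: float
    edf: float
    rss: float  # unweighted residual sum of squares over subjects x grid
    gcv: float

    @property
    def q(self) -> int:
        return self.theta.shape[0]

    def coef_cov(self, j) -> np.ndarray:
        """Grid covariance of one coefficient function beta_j(.)."""
        j = self.design.column(j)
        K = self.B.shape[1]
        block = self.cov_theta[j * K : (j + 1) * K, j * K : (j + 1) * K]
        return self.B @ block @ self.B.T

    def residuals(self) -> np.ndarray:
        return self.design.Y - self.design.X @ self.theta @ self.B.T


def _solve_penalized(X, Y, B, P, W, lam):
    """Penalized (G)LS normal equations; returns theta, edf and diagnostics."""
    n, q = X.shape
    K = B.shape[1]
    XtX = X.T @ X
    Gw = B.T @ W @ B
    M0 = np.kron(XtX, Gw)
    A = M0 + lam * np.kron(np.eye(q), P)
    rhs = (B.T @ W @ Y.T @ X).ravel(order="F")
    try:
        c, low = linalg.cho_factor(A)
        theta = linalg.cho_solve((c, low), rhs)
        Ainv = linalg.cho_solve((c, low), np.eye(A.shape[0]))
    except linalg.LinAlgError as err:
        cond = np.linalg.cond(A)
        raise linalg.LinAlgError(
            f"singular penalized normal equations (cond={cond:.3e}); "
            "check covariate collinearity or increase the penalty"
        ) from err
    Theta = theta.reshape(q, K)
    fitted = X @ Theta @ B.T
    resid = Y - fitted
    rss_w = float(np.sum((resid @ W) * resid))
    edf = float(np.trace(Ainv @ M0))
    return Theta, Ainv, M0, resid, rss_w, edf


def _gcv_search(X, Y, B, P, W, lambda_grid):
    n, T = Y.shape
    best = None
    for lam in lambda_grid:
        Theta, Ainv, M0, resid, rss_w, edf = _solve_penalized(X, Y, B, P, W, lam)
        denom = max(n * T - edf, 1.0)
        gcv = n * T * rss_w / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, Theta, Ainv, M0, resid, edf)
    return best


def _estimate_sigma(resid, q, B, structure, shrinkage):
    """Residual covariance over the grid and its inverse (the GLS weight).

    ``"basis"`` (default): a structured estimate — an unrestricted K x K
    covariance of the residuals' basis-coefficient scores plus an isotropic
    variance for the off-span remainder. With K basis functions and m = n - q
    residual functions, the within-span block is estimated from an m-sample,
    K-dimensional problem (well-conditioned when K << n), unlike a raw
    T x T inverse whose spectrum is dominated by sampling noise when the
    number of bins approaches the number of subjects.
    ``"shrunk_diagonal"``: the sample covariance blended with its diagonal by
    ``shrinkage`` (anticonservative standard errors when T is close to n;
    retained for comparison).
    Returns ``(Sigma, W)`` with ``W = Sigma^{-1}`` exactly.
    """
    n, T = resid.shape
    dof = max(n - q, 1)
    if structure == "shrunk_diagonal":
        S = resid.T @ resid / dof
        Sig = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
        try:
            linalg.cholesky(Sig)
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError(
                "residual covariance not positive definite after shrinkage"
            ) from err
        W = linalg.inv(Sig)
        return Sig, (W + W.T) / 2.0
    if structure != "basis":
        raise ValueError(f"unknown cov_structure {structure!r}")

    K = B.shape[1]
    Bc = B @ linalg.inv(B.T @ B)  # dual basis: Bc.T @ B = I_K
    scores = resid @ Bc  # (n, K) basis-coefficient residuals
    Sig_K = scores.T @ scores / dof
    span_resid = scores @ B.T
    off = resid - span_resid
    off_dim = max(T - K, 1)
    sigma_perp2 = float(np.sum(off**2)) / (dof * off_dim)
    sigma_perp2 = max(sigma_perp2, 1e-12)
    try:
        W_K = linalg.inv(Sig_K)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "singular within-span residual covariance (need n - q > n_basis)"
        ) from err
    Pb = B @ Bc.T
    P_perp = np.eye(T) - Pb
    Sig = B @ Sig_K @ B.T + sigma_perp2 * P_perp
    W = Bc @ W_K @ Bc.T + P_perp / sigma_perp2
    return Sig, (W + W.T) / 2.0


def fit_fosr(
    design: FunctionalDesign,
    penalty_order: int = 2,
    lambdas: float | None = None,
    lambda_grid: np.ndarray | None = None,
    cov_structure: str = "basis",
    shrinkage: float = 0.1,
) -> FOSRFit:
    """Three-step penalized-GLS FOSR fit.

    1. Penalized OLS with the smoothing parameter chosen by GCV.
    2. Estimate the residual covariance over the grid from step-1 residuals
       (see ``cov_structure``; ``"identity"`` skips weighting).
    3. Re-estimate by penalized GLS with the inverse covariance as weight,
       re-selecting the smoothing parameter by weighted GCV.

    ``lambdas`` fixes the smoothing parameter instead of searching (0 gives an
    unpenalized fit). The reported coefficient covariance is a
    degrees-of-freedom-corrected robust sandwich of the final weighted fit.
    """
    X, Y, grid = design.X, design.Y, design.grid
    n, q = X.shape
    T = Y.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        # identify an offending column for the error message
        bad = None
        for j in range(q):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad = design.col_names[j]
                break
        raise linalg.LinAlgError(f"collinear design matrix (column {bad!r} redundant)")

    B, P = build_basis(
        grid, design.n_basis, periodic=design.periodic, family=design.family,
        penalty_order=penalty_order,
    )
    if lambda_grid is None:
        lambda_grid = np.logspace(-2, 8, 26)
    fixed_lambda = lambdas is not None

    def one_pass(W):
        if fixed_lambda:
            Theta, Ainv, M0, resid, rss_w, edf = _solve_penalized(
                X, Y, B, P, W, float(lambdas)
            )
            denom = max(n * T - edf, 1.0)
            return (n * T * rss_w / denom**2, float(lambdas), Theta, Ainv, M0, resid, edf)
        return _gcv_search(X, Y, B, P, W, lambda_grid)

    # step 1: working-independence fit
    W = np.eye(T)
    gcv, lam, Theta, Ainv, M0, resid, edf = one_pass(W)

    if cov_structure == "identity":
        sigma2 = float(np.sum(resid**2) / max(n * T - edf, 1.0))
        Sigma = sigma2 * np.eye(T)
        cov_theta = sigma2 * (Ainv @ M0 @ Ainv)
    else:
        # steps 2-3: estimate Sigma, refit with GLS weight
        Sigma, W = _estimate_sigma(resid, q, B, cov_structure, shrinkage)
        gcv, lam, Theta, Ainv, M0, resid, edf = one_pass(W)
        # robust sandwich: the middle re-estimates the weighted score
        # covariance from the final residuals, with the Wishart
        # degrees-of-freedom correction m/(m - K - 1) compensating the
        # variance cost of plugging in an estimated weight matrix
        m = max(n - q, 1)
        K = B.shape[1]
        S_raw = resid.T @ resid / m
        mid = np.kron(X.T @ X, B.T @ W @ S_raw @ W @ B)
        correction = m / (m - K - 1) if m > K + 1 else 2.0
        cov_theta = min(correction, 2.0) * (Ainv @ mid @ Ainv)

    coef = Theta @ B.T
    K = B.shape[1]
    se = np.empty_like(coef)
    for j in range(q):
        block = cov_theta[j * K : (j + 1) * K, j * K : (j + 1) * K]
        se[j] = np.sqrt(np.maximum(np.einsum("tk,kl,tl->t", B, block, B), 0.0))
    return FOSRFit(
        design=design,
        B=B,
        P=P,
        theta=Theta,
        coef=coef,
        se=se,
        cov_theta=cov_theta,
        Sigma=Sigma,
        W=W,
        lambda_=float(lam),
        edf=edf,
        rss=float(np.sum(resid**2)),
        gcv=float(gcv),
    )


# --------------------------------------------------------------------------- bands


@dataclass
class Band:
    j: int
    name: str
    kind: str  # "pointwise" | "simultaneous"
    alpha: float
    estimate: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    critical: float  # z or the simulated max-statistic quantile q*


def pointwise_band(fit: FOSRFit, j, alpha: float = 0.05) -> Band:
    """Per-point interval beta_j(t) +/- z_{1-alpha/2} SE_j(t)."""
    j = fit.design.column(j)
    z = float(norm.ppf(1.0 - alpha / 2.0))
    est, se = fit.coef[j], fit.se[j]
    return Band(
        j=j, name=fit.design.col_names[j], kind="pointwise", alpha=alpha,
        estimate=est, lo=est - z * se, hi=est + z * se, critical=z,
    )


def simultaneous_band(
    fit: FOSRFit, j, alpha: float = 0.05, n_sim: int = 10_000, seed: int | None = None
) -> Band:
    """Simultaneous band via the Gaussian max-statistic construction.

    Draws from the estimated covariance of beta_j(.) on the grid, takes the
    (1-alpha) quantile q* of max_t |draw(t)|/SE_j(t), and widens the pointwise
    band to +/- q* SE. q* is floored at the pointwise z so the simultaneous
    band always contains the pointwise band. Deterministic given ``seed``.
    """
    jj = fit.design.column(j)
    C = fit.coef_cov(jj)
    se = fit.se[jj]
    if np.any(se <= 0):
        raise ValueError("zero pointwise SE: simultaneous band undefined")
    vals, vecs = linalg.eigh((C + C.T) / 2.0)
    if vals.min() < -1e-8 * max(vals.max(), 1.0):
        raise linalg.LinAlgError("coefficient covariance is not PSD")
    vals = np.maximum(vals, 0.0)
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_sim, len(vals))) @ (vecs * np.sqrt(vals)).T
    m = np.max(np.abs(draws) / se[None, :], axis=1)
    z = float(norm.ppf(1.0 - alpha / 2.0))
    qstar = max(float(np.quantile(m, 1.0 - alpha)), z)
    est = fit.coef[jj]
    return Band(
        j=jj, name=fit.design.col_names[jj], kind="simultaneous", alpha=alpha,
        estimate=est, lo=est - qstar * se, hi=est + qstar * se, critical=qstar,
    )


# --------------------------------------------------------------------------- tests


def global_f_test(
    design: FunctionalDesign,
    j,
    fit: FOSRFit | None = None,
    n_perm: int = 1999,
    seed: int | None = None,
    **fit_kwargs,
):
    """Permutation global F-test for one covariate's coefficient function.

    F compares the residual sum of squares, summed over the grid, of the full
    model and of the model with covariate ``j`` removed, on effective degrees
    of freedom; the p-value comes from permuting covariate ``j``'s column
    across subjects (the smoothing parameter and GLS weight are held at their
    observed-fit values during permutation). Deterministic given ``seed``.
    """
    jj = design.column(j)
    if jj == 0:
        raise ValueError("the intercept function has no F-test")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} < 99: permutation p unstable", stacklevel=2)
    if fit is None:
        fit = fit_fosr(design, **fit_kwargs)
    X, Y = design.X, design.Y
    n, q = X.shape
    T = Y.shape[1]
    lam, W, B, P = fit.lambda_, fit.W, fit.B, fit.P

    def rss_and_edf(Xm):
        Theta, Ainv, M0, resid, _, edf = _solve_penalized(Xm, Y, B, P, W, lam)
        return float(np.sum(resid**2)), edf

    def f_stat(Xm):
        rss_full, edf_full = rss_and_edf(Xm)
        rss_red, edf_red = rss_and_edf(np.delete(Xm, jj, axis=1))
        df1 = max(edf_full - edf_red, 1e-8)
        df2 = max(n * T - edf_full, 1.0)
        return ((rss_red - rss_full) / df1) / (rss_full / df2)

    f_obs = f_stat(X)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[:, jj] = Xp[rng.permutation(n), jj]
        if f_stat(Xp) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return float(f_obs), float(p)


# --------------------------------------------------------------------------- windows


@dataclass
class Window:
    start_hours: float
    end_hours: float
    sign: int
    n_bins: int

    @property
    def start_clock(self) -> str:
        return hours_to_clock(self.start_hours)

    @property
    def end_clock(self) -> str:
        return hours_to_clock(self.end_hours % 24.0)

    def __str__(self) -> str:  # e.g. "23:30-03:00 (-)"
        s = "+" if self.sign > 0 else "-"
        return f"{self.start_clock}-{self.end_clock} ({s})"


def significant_windows(band: Band, grid, bin_minutes: int | None = None) -> list[Window]:
    """Maximal runs of bins whose band excludes zero, merged across midnight.

    Each window is reported as [bin start clock, bin end clock] with the sign
    of the effect; a run touching both ends of the day with a consistent sign
    becomes a single wrapped window (e.g. 23:30-03:00).
    """
    grid = np.asarray(grid, dtype=float)
    if bin_minutes is None:
        bin_minutes = int(round((grid[1] - grid[0]) * 60)) if len(grid) > 1 else 30
    half = bin_minutes / 60.0 / 2.0
    sign = np.where(band.lo > 0, 1, np.where(band.hi < 0, -1, 0))
    runs = []
    start = None
    for i, s in enumerate(sign):
        if s != 0 and (start is None or s != sign[i - 1]):
            if start is not None:
                runs.append((start, i - 1))
            start = i
        elif s == 0 and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(sign) - 1))

    # merge the first and last runs across the midnight wrap
    if (
        len(runs) >= 2
        and runs[0][0] == 0
        and runs[-1][1] == len(sign) - 1
        and sign[0] == sign[-1]
    ):
        s0, e0 = runs.pop(0)
        s1, e1 = runs.pop(-1)
        runs.append((s1, e0 + len(sign)))  # wrapped run

    windows = []
    for s, e in runs:
        n_bins = e - s + 1
        start_h = grid[s % len(sign)] - half
        end_h = grid[e % len(sign)] + half
        if e >= len(sign):  # wrapped
            end_h = grid[e % len(sign)] + half
        windows.append(
            Window(
                start_hours=start_h % 24.0,
                end_hours=end_h if e < len(sign) else end_h,
                sign=int(sign[s % len(sign)]),
                n_bins=n_bins,
            )
        )
    windows.sort(key=lambda w: w.start_hours)
    return windows
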