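"""Functional multiway ANOVA with penalized B-spline coefficient curves.

Each trait trajectory is modeled as

    y_i(t) = mu(t) + sum_j x_ij' a_j(t) [+ interaction terms] + eps_i(t),

where every coefficient curve is expanded in a shared cubic B-spline basis on
the union grid of observation days.  Stacking one regression row
``z_i (x) B(t_ij)`` per observed (plant, day) pair gives an ordinary linear
model in the spline coefficients; a single roughness penalty
``lambda * I_p (x) Omega`` (Omega = integrated products of basis second
derivatives) shrinks every curve toward a straight line, with the common
``lambda`` chosen by generalized cross-validation.  The estimator is linear
in the responses, so its covariance follows from the (estimated) covariance
of the error process; temporal dependence is handled through a
pairwise-complete covariance surface of the residual curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .traits import TraitMatrix

__all__ = [
    "SplineBasis",
    "DesignSpec",
    "FanovaFit",
    "RankError",
    "make_basis",
    "penalty_matrix",
    "parse_formula",
    "build_design",
    "gcv_score",
    "fanova_fit",
    "coef_covariance",
    "predict_curve",
    "DEFAULT_LAMBDA_GRID",
]

#: 40 log-spaced candidate smoothing parameters; ties in GCV go to the
#: smallest value.
DEFAULT_LAMBDA_GRID = np.logspace(-6, 4, 40)


class RankError(np.linalg.LinAlgError):
    """Design or penalized normal equations are (numerically) rank deficient."""


@dataclass(frozen=True)
class SplineBasis:
    """Clamped B-spline basis on [domain[0], domain[1]].

    The rank (number of basis functions) is ``K = degree + 1 + n_interior``.
    """

    degree: int
    interior: np.ndarray
    domain: tuple

    def __post_init__(self):
        object.__setattr__(self, "interior", np.asarray(self.interior, dtype=np.float64))
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("degenerate domain")
        if self.interior.size and not (
            np.all(np.diff(self.interior) > 0)
            and self.interior[0] > lo
            and self.interior[-1] < hi
        ):
            raise ValueError("interior knots must be sorted strictly inside the domain")

    @property
    def K(self) -> int:
        return self.degree + 1 + self.interior.size

    @property
    def knots(self) -> np.ndarray:
        lo, hi = self.domain
        return np.concatenate([[lo] * (self.degree + 1), self.interior, [hi] * (self.degree + 1)])

    def _check_domain(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        lo, hi = self.domain
        if t.min() < lo or t.max() > hi:
            raise ValueError(f"evaluation points outside basis domain [{lo}, {hi}]")
        return t

    def design(self, t) -> np.ndarray:
        """(len(t), K) matrix of basis function values; no extrapolation."""
        t = self._check_domain(t)
        return BSpline.design_matrix(t, self.knots, self.degree).toarray()

    def deriv2(self, t) -> np.ndarray:
        """(len(t), K) matrix of basis second derivatives."""
        t = self._check_domain(t)
        b = BSpline(self.knots, np.eye(self.K), self.degree)
        return b.derivative(2)(t)


def make_basis(days, degree: int = 3, n_interior: int | None = None) -> SplineBasis:
    """Basis on the union day grid with the default knot rule.

    With ``m`` distinct days the default places ``floor(m/2) - 4`` equally
    spaced interior knots, giving rank ``K = degree + 1 + floor(m/2) - 4``
    (14 basis functions for m = 28 cubic splines).  Pass ``n_interior``
    explicitly for short series where the rule would go negative.
    """
    days = np.unique(np.asarray(days, dtype=np.float64))
    m = days.size
    if m < 2:
        raise ValueError("need at least 2 distinct days")
    if n_interior is None:
        n_interior = m // 2 - 4
        if n_interior < 0:
            raise ValueError(
                f"default knot rule gives {n_interior} interior knots for m={m}; "
                "supply n_interior explicitly"
            )
    if n_interior < 0:
        raise ValueError("n_interior must be >= 0")
    interior = np.linspace(days[0], days[-1], n_interior + 2)[1:-1]
    return SplineBasis(degree, interior, (float(days[0]), float(days[-1])))


def penalty_matrix(basis: SplineBasis) -> np.ndarray:
    """Roughness penalty Omega with entries integral of B''_u B''_v over the domain.

    The integrand is piecewise polynomial of degree 2(degree - 2) on each
    inter-knot interval, so per-interval Gauss-Legendre quadrature with
    ``degree`` nodes is exact.
    """
    if basis.degree < 2:
        raise ValueError("second-derivative penalty needs degree >= 2")
    breaks = np.unique(basis.knots)
    nodes, wts = leggauss(max(basis.degree, 2))
    K = basis.K
    omega = np.zeros((K, K))
    for a, b in zip(breaks[:-1], breaks[1:]):
        t = 0.5 * (b - a) * nodes + 0.5 * (a + b)
        d2 = basis.deriv2(t)
        omega += 0.5 * (b - a) * (d2.T * wts) @ d2
    return 0.5 * (omega + omega.T)


@dataclass(frozen=True)
class DesignSpec:
    """Main effects (in declaration order) and optional pairwise interactions."""

    mains: tuple
    interactions: tuple = ()
    response: str | None = None

    def __post_init__(self):
        if not self.mains:
            raise ValueError("at least one main effect is required")
        for f1, f2 in self.interactions:
            if f1 not in self.mains or f2 not in self.mains:
                raise ValueError(f"interaction {f1}:{f2} references an undeclared factor")


def parse_formula(formula: str) -> DesignSpec:
    """Parse e.g. ``"size ~ genotype + block"`` or ``"y ~ A + B + A:B"``."""
    response = None
    rhs = formula
    if "~" in formula:
        lhs, rhs = formula.split("~", 1)
        response = lhs.strip() or None
    mains, interactions = [], []
    for term in rhs.split("+"):
        term = term.strip()
        if not term:
            raise ValueError(f"empty term in formula {formula!r}")
        if ":" in term:
            f1, f2 = (s.strip() for s in term.split(":", 1))
            interactions.append((f1, f2))
        else:
            mains.append(term)
    return DesignSpec(tuple(mains), tuple(interactions), response)


def _levels(col: pd.Series):
    if isinstance(col.dtype, pd.CategoricalDtype):
        return [lv for lv in col.cat.categories if (col == lv).any()]
    return list(pd.unique(col))


def _indicator_block(col: pd.Series, name: str):
    """Baseline-coded indicators: one column per non-first level."""
    levels = _levels(col)
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has a single level")
    cols = np.column_stack([(col == lv).to_numpy(float) for lv in levels[1:]])
    names = [f"{name}[{lv}]" for lv in levels[1:]]
    return cols, names


def build_design(factors: pd.DataFrame, spec: DesignSpec):
    """Design matrix with intercept, baseline-coded mains, then interactions.

    The first observed level of each factor is the baseline and is dropped;
    an interaction block is the elementwise Kronecker product of the two
    factors' indicator blocks.  Returns ``(X, column_names)``.
    """
    for f in spec.mains:
        if f not in factors.columns:
            raise ValueError(f"unknown factor {f!r}")
    n = len(factors)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    main_blocks = {}
    for f in spec.mains:
        cols, nms = _indicator_block(factors[f], f)
        main_blocks[f] = (cols, nms)
        blocks.append(cols)
        names.extend(nms)
    for f1, f2 in spec.interactions:
        c1, n1 = main_blocks[f1]
        c2, n2 = main_blocks[f2]
        inter = np.einsum("ni,nj->nij", c1, c2).reshape(n, -1)
        blocks.append(inter)
        names.extend(f"{a}:{b}" for a in n1 for b in n2)
    X = np.hstack(blocks)
    return X, names


def gcv_score(lam: float, y: np.ndarray, Z: np.ndarray, penalty: np.ndarray) -> float:
    """GCV(lambda) = N * RSS / (N - tr H)^2 for the penalized fit
    ``beta = (Z'Z + lam * penalty)^{-1} Z'y``; +inf when tr H >= N."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = np.asarray(y, dtype=np.float64)
    ZtZ = Z.T @ Z
    M = ZtZ + lam * penalty
    try:
        f = cho_factor(M)
    except np.linalg.LinAlgError as exc:
        raise RankError("penalized normal equations not positive definite") from exc
    beta = cho_solve(f, Z.T @ y)
    rss = float(np.sum((y - Z @ beta) ** 2))
    tr_h = float(np.trace(cho_solve(f, ZtZ)))
    n = y.size
    if tr_h >= n:
        return np.inf
    return n * rss / (n - tr_h) ** 2


@dataclass
class FanovaFit:
    """Fitted functional ANOVA.

    ``beta`` is the stacked coefficient vector (length p*K) partitioned into
    one K-block per design column (column 1 is the intercept curve);
    ``A`` is the smoother operator with ``beta = A @ y_stacked``.
    """

    basis: SplineBasis
    design: np.ndarray
    colnames: list
    beta: np.ndarray
    lam: float
    lam_grid: np.ndarray
    gcv: np.ndarray
    A: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    row_plant: np.ndarray
    row_dayidx: np.ndarray
    trH: float
    Y: TraitMatrix
    cov: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.design.shape[1]

    @property
    def K(self) -> int:
        return self.basis.K

    @property
    def N(self) -> int:
        return self.y.size

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fitted

    @property
    def beta_blocks(self) -> np.ndarray:
        """(p, K) view: one spline coefficient block per design column."""
        return self.beta.reshape(self.p, self.K)

    def column_index(self, name: str) -> int:
        return self.colnames.index(name)


def _stack_rows(Y: TraitMatrix, X: np.ndarray, basis: SplineBasis):
    B_all = basis.design(Y.days)
    rows, ys, plants, dayidx = [], [], [], []
    for i in range(Y.n_plants):
        obs = Y.observed[i]
        if not obs.any():
            continue
        B = B_all[obs]
        rows.append(np.einsum("p,mk->mpk", X[i], B).reshape(B.shape[0], -1))
        ys.append(Y.values[i, obs])
        plants.append(np.full(B.shape[0], i))
        dayidx.append(np.nonzero(obs)[0])
    Z = np.vstack(rows)
    return Z, np.concatenate(ys), np.concatenate(plants), np.concatenate(dayidx), B_all


def fanova_fit(
    Y: TraitMatrix,
    formula: str | DesignSpec,
    factors: pd.DataFrame | None = None,
    lam_grid=None,
    degree: int = 3,
    n_interior: int | None = None,
    basis: SplineBasis | None = None,
) -> FanovaFit:
    """Fit the functional ANOVA by penalized least squares with GCV-chosen lambda.

    Missing cells of the trait matrix simply contribute no regression rows.
    ``factors`` defaults to the trait matrix's plant metadata (genotype,
    block).  Raises :class:`RankError` when the factor design is rank
    deficient, and ``ValueError`` when some basis function has no observed
    day in its support.
    """
    spec = parse_formula(formula) if isinstance(formula, str) else formula
    if factors is None:
        factors = Y.meta
    if basis is None:
        basis = make_basis(Y.days, degree=degree, n_interior=n_interior)
    lam_grid = DEFAULT_LAMBDA_GRID if lam_grid is None else np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(lam_grid < 0):
        raise ValueError("lambda must be >= 0")

    X, names = build_design(factors, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("factor design matrix is rank deficient")

    Z, y, row_plant, row_dayidx, B_all = _stack_rows(Y, X, basis)
    obs_days = np.unique(row_dayidx)
    if np.any(np.abs(B_all[obs_days]).sum(axis=0) == 0):
        raise ValueError("a basis function has no observed day in its support")

    omega = penalty_matrix(basis)
    p = X.shape[1]
    D = np.kron(np.eye(p), omega)
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    N = y.size

    scores = np.empty(lam_grid.size)
    for idx, lam in enumerate(lam_grid):
        try:
            f = cho_factor(ZtZ + lam * D)
        except np.linalg.LinAlgError:
            scores[idx] = np.inf
            continue
        beta = cho_solve(f, Zty)
        rss = float(np.sum((y - Z @ beta) ** 2))
        tr_h = float(np.trace(cho_solve(f, ZtZ)))
        scores[idx] = np.inf if tr_h >= N else N * rss / (N - tr_h) ** 2
    if not np.isfinite(scores).any():
        raise RankError("no lambda on the grid yields a valid fit")
    best = int(np.argmin(scores))  # argmin returns the first (smallest lambda) tie
    lam = float(lam_grid[best])

    try:
        f = cho_factor(ZtZ + lam * D)
    except np.linalg.LinAlgError as exc:
        raise RankError("penalized normal equations not positive definite") from exc
    A = cho_solve(f, Z.T)
    beta = A @ y
    trH = float(np.trace(cho_solve(f, ZtZ)))
    return FanovaFit(
        basis=basis,
        design=X,
        colnames=names,
        beta=beta,
        lam=lam,
        lam_grid=lam_grid,
        gcv=scores,
        A=A,
        y=y,
        fitted=Z @ beta,
        row_plant=row_plant,
        row_dayidx=row_dayidx,
        trH=trH,
        Y=Y,
    )


def _pairwise_covariance(R: np.ndarray) -> np.ndarray:
    """Pairwise-complete sample covariance of residual curves (NaN = missing).

    Day pairs with fewer than 2 joint observations are imputed from the mean
    covariance at the nearest estimable lag, with a warning.
    """
    W = (~np.isnan(R)).astype(np.float64)
    Rz = np.nan_to_num(R)
    counts = W.T @ W
    S = Rz.T @ Rz
    SA = Rz.T @ W  # SA[a, b] = sum of residuals at day a over plants observed at a and b
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (S - SA * SA.T / counts) / (counts - 1)
    bad = counts < 2
    if bad.any():
        m = R.shape[1]
        lags = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        lag_mean = np.full(m, np.nan)
        for ell in range(m):
            sel = (lags == ell) & ~bad
            if sel.any():
                lag_mean[ell] = cov[sel].mean()
        est_lags = np.nonzero(~np.isnan(lag_mean))[0]
        if est_lags.size == 0:
            raise ValueError("no day pair has 2 joint observations")
        warnings.warn(
            f"{int(bad.sum())} covariance entries had <2 joint observations; "
            "imputed from the nearest estimable lag",
            stacklevel=3,
        )
        for a, b in zip(*np.nonzero(bad)):
            nearest = est_lags[np.argmin(np.abs(est_lags - lags[a, b]))]
            cov[a, b] = lag_mean[nearest]
    return 0.5 * (cov + cov.T)


def _plant_blocks(fit: FanovaFit):
    """Per-plant stacked-row indices, day indices, and smoother columns."""
    blocks = []
    for i in range(fit.Y.n_plants):
        rows = np.nonzero(fit.row_plant == i)[0]
        if rows.size == 0:
            continue
        idx = fit.row_dayidx[rows]
        Ai = fit.A[:, rows]
        Zi = np.einsum("p,mk->mpk", fit.design[i], fit.basis.design(fit.Y.days[idx])).reshape(
            rows.size, -1
        )
        blocks.append((idx, Ai, Zi))
    return blocks


def _coef_cov_from_sigma(blocks, sigma: np.ndarray, pk: int) -> np.ndarray:
    cov = np.zeros((pk, pk))
    for idx, Ai, _ in blocks:
        cov += Ai @ sigma[np.ix_(idx, idx)] @ Ai.T
    return 0.5 * (cov + cov.T)


def _debias_sigma(blocks, c_hat: np.ndarray, pk: int, n_iter: int = 10, tol: float = 1e-4):
    """Method-of-moments de-biasing of the residual covariance surface.

    The residuals are ``r = (I - H) eps``, so their covariance understates
    the error covariance by the part the smoother absorbs — substantially so
    for temporally correlated errors, which look smooth to the fit.  For a
    candidate error surface ``sigma`` the implied per-plant residual
    covariance is

        E[r_i r_i'] = S_i - Z_i A_i S_i - (Z_i A_i S_i)' + Z_i Cov(beta) Z_i'

    with ``S_i`` the restriction of ``sigma`` to plant i's days.  We iterate
    ``sigma <- sigma + (c_hat - M(sigma))``, where ``M`` aggregates the
    implied residual covariances over plants on the union grid, until the
    implied surface matches the observed pairwise covariance.
    """
    m = c_hat.shape[0]
    sigma = c_hat.copy()
    for _ in range(n_iter):
        cov_beta = _coef_cov_from_sigma(blocks, sigma, pk)
        num = np.zeros((m, m))
        cnt = np.zeros((m, m))
        for idx, Ai, Zi in blocks:
            Si = sigma[np.ix_(idx, idx)]
            ZAS = Zi @ (Ai @ Si)
            Ei = Si - ZAS - ZAS.T + Zi @ cov_beta @ Zi.T
            num[np.ix_(idx, idx)] += Ei
            cnt[np.ix_(idx, idx)] += 1.0
        implied = np.divide(num, cnt, out=np.zeros_like(num), where=cnt > 0)
        step = np.where(cnt > 0, c_hat - implied, 0.0)
        sigma = sigma + step
        denom = max(np.abs(c_hat).max(), 1e-12)
        if np.abs(step).max() / denom < tol:
            break
    return sigma


def coef_covariance(fit: FanovaFit, df_correction: bool = True) -> np.ndarray:
    """Plug-in covariance of the stacked spline coefficients.

    The error covariance surface is the pairwise-complete sample covariance
    of the residual curves across plants; with ``df_correction`` (default) it
    is de-biased by moment matching for the part of the error process the
    smoother absorbed (see :func:`_debias_sigma`), then projected onto the
    positive semidefinite cone.  With V block-diagonal over plants,
    ``Cov(beta) = A V A'``.  The result is cached on ``fit.cov``.
    """
    R = np.full((fit.Y.n_plants, fit.Y.days.size), np.nan)
    R[fit.row_plant, fit.row_dayidx] = fit.residuals
    sigma = _pairwise_covariance(R)
    blocks = _plant_blocks(fit)
    pk = fit.beta.size
    if df_correction:
        sigma = _debias_sigma(blocks, sigma, pk)
    # pairwise-complete estimates need not be PSD; clip negative eigenvalues
    evals, evecs = np.linalg.eigh(sigma)
    sigma = (evecs * np.clip(evals, 0.0, None)) @ evecs.T

    cov = _coef_cov_from_sigma(blocks, sigma, pk)
    fit.cov = cov
    return cov


def predict_curve(fit: FanovaFit, design_row, tgrid) -> np.ndarray:
    """Evaluate ``sum_c design_row_c * B(t)' beta_c`` on a time grid.

    ``design_row = e_1`` gives the intercept curve; a plant's own design row
    gives its fitted mean trajectory.  No extrapolation outside the basis
    domain.
    """
    design_row = np.asarray(design_row, dtype=np.float64)
    if design_row.shape != (fit.p,):
        raise ValueError(f"design_row must have length {fit.p}")
    B = fit.basis.design(tgrid)
    return B @ (fit.beta_blocks.T @ design_row)
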