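"""Pointwise confidence bands for effect curves, and simulation tools.

A contrast vector ``L`` over design columns defines the curve
``sum_c L_c a_c(t)``; its plug-in variance at each time point follows from
the coefficient covariance, and the band is the pointwise Gaussian interval
``estimate(t) +/- z * SE(t)``.  Bands are pointwise, not simultaneous.

Column indices in :func:`ci_contrast` are 1-based (column 1 is the
intercept), matching how design-matrix columns are usually reported for this
model.  Passing the intercept as one of the two indices compares the other
column's level against the baseline level, whose effect is identically zero —
e.g. with 140 genotypes and 3 blocks, ``j1 = 142, j2 = 1`` yields the band
for the block-3 effect curve itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fanova import FanovaFit, coef_covariance, fanova_fit, predict_curve
from .traits import TraitMatrix

__all__ = [
    "CurveBand",
    "SynthGrowthConfig",
    "ci",
    "ci_contrast",
    "synth_growth",
    "coverage_sim",
    "CoverageResult",
    "significance_summary",
]

DEFAULT_LEVEL = 0.95


@dataclass(frozen=True)
class CurveBand:
    """A curve estimate with pointwise lower/upper confidence limits."""

    tgrid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self):
        for name in ("tgrid", "estimate", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if not (self.tgrid.shape == self.estimate.shape == self.lower.shape == self.upper.shape):
            raise ValueError("band arrays must share one shape")
        if np.any(self.lower > self.estimate + 1e-12) or np.any(self.upper < self.estimate - 1e-12):
            raise ValueError("band must bracket the estimate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.tgrid, "estimate": self.estimate, "lower": self.lower, "upper": self.upper}
        )


def _cov(fit: FanovaFit) -> np.ndarray:
    return fit.cov if fit.cov is not None else coef_covariance(fit)


def ci(fit: FanovaFit, L, level: float = DEFAULT_LEVEL, tgrid=None) -> CurveBand:
    """Pointwise band for the linear combination of effect curves given by ``L``.

    ``L = e_1`` gives the intercept curve; ``L = (1, 0, ..., 0, 1/3, 1/3)``
    under a genotype + 3-block model gives the baseline genotype's growth
    curve averaged over the blocks.
    """
    L = np.asarray(L, dtype=np.float64)
    if L.shape != (fit.p,):
        raise ValueError(f"contrast vector must have length {fit.p}, got {L.shape}")
    if not np.all(np.isfinite(L)):
        raise ValueError("contrast vector entries must be finite")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tgrid = np.asarray(fit.Y.days if tgrid is None else tgrid, dtype=np.float64)

    est = predict_curve(fit, L, tgrid)
    B = fit.basis.design(tgrid)
    U = np.einsum("p,tk->tpk", L, B).reshape(tgrid.size, -1)
    var = np.clip(np.einsum("ti,ij,tj->t", U, _cov(fit), U), 0.0, None)
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    half = z * np.sqrt(var)
    return CurveBand(tgrid, est, est - half, est + half, level)


def ci_contrast(fit: FanovaFit, j1: int, j2: int, level: float = DEFAULT_LEVEL, tgrid=None) -> CurveBand:
    """Band for the difference between the effect curves of two design columns.

    ``j1`` and ``j2`` are 1-based column indices.  The intercept column (1)
    stands for the baseline level of any factor, whose effect curve is
    identically zero, so it contributes nothing to the contrast:
    ``j1 = k, j2 = 1`` gives the band for column k's effect itself, and
    ``j1 = 1, j2 = k`` its negative.  ``j1 = j2`` gives the zero curve with
    zero width.
    """
    p = fit.p
    for j in (j1, j2):
        if not 1 <= j <= p:
            raise ValueError(f"column index {j} out of range 1..{p}")
    tg = np.asarray(fit.Y.days if tgrid is None else tgrid, dtype=np.float64)
    if j1 == j2:
        zero = np.zeros(tg.size)
        return CurveBand(tg, zero, zero, zero, level)
    L = np.zeros(p)
    if j1 != 1:
        L[j1 - 1] += 1.0
    if j2 != 1:
        L[j2 - 1] -= 1.0
    return ci(fit, L, level=level, tgrid=tg)


# --- synthetic growth data -------------------------------------------------


def _logistic(t, amp, rate, mid):
    return amp / (1.0 + np.exp(-rate * (t - mid)))


def _default_mu(t):
    return _logistic(t, 10.0, 0.25, 20.0)


def _default_genotype_effect(k):
    # deterministic family of smooth logistic + sinusoidal perturbations
    def g(t, k=k):
        return 0.6 * math.cos(k) * _logistic(t, 1.0, 0.25, 20.0) + 0.4 * math.sin(k + 1.0) * np.sin(
            np.pi * (t - 1.0) / 43.0
        )

    return g


def _default_block_effect(k):
    def p(t, k=k):
        return 0.25 * k * _logistic(t, 1.0, 0.2, 22.0) + 0.15 * np.sin(np.pi * k * (t - 1.0) / 86.0)

    return p


@dataclass
class SynthGrowthConfig:
    """Generator for growth trajectories under a genotype + block design.

    One plant per (genotype, block, replicate); trajectories follow
    ``mu(t) + g_genotype(t) + p_block(t)`` plus an AR(1) Gaussian error
    process on the union day grid (marginal sd ``sigma``, lag-1 correlation
    ``rho`` between consecutive grid days).  Each plant retains each day
    independently with probability ``retention``, emulating irregular imaging
    schedules; a plant that would lose every day is redrawn (with a warning).
    True effect curves default to smooth logistic/sinusoidal shapes on the
    day range 1..44.
    """

    n_genotypes: int = 10
    n_blocks: int = 3
    n_replicates: int = 1
    m_days: int = 20
    day_range: tuple = (1.0, 44.0)
    retention: float = 0.8
    sigma: float = 0.5
    rho: float = 0.6
    seed: int = 0
    mu: object = None
    genotype_effects: list | None = None  # effect curves for levels 2..n_genotypes
    block_effects: list | None = None  # effect curves for levels 2..n_blocks

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not -1 < self.rho < 1:
            raise ValueError("|rho| must be < 1")
        if not 0 < self.retention <= 1:
            raise ValueError("retention must be in (0, 1]")
        if self.mu is None:
            self.mu = _default_mu
        if self.genotype_effects is None:
            self.genotype_effects = [_default_genotype_effect(k) for k in range(2, self.n_genotypes + 1)]
        if self.block_effects is None:
            self.block_effects = [_default_block_effect(k) for k in range(2, self.n_blocks + 1)]
        if len(self.genotype_effects) != self.n_genotypes - 1:
            raise ValueError("need one genotype effect curve per non-baseline level")
        if len(self.block_effects) != self.n_blocks - 1:
            raise ValueError("need one block effect curve per non-baseline level")


def ar1_noise(rng, n_series: int, m: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with marginal sd ``sigma`` and lag-1 correlation ``rho``."""
    eps = np.empty((n_series, m))
    if sigma == 0:
        eps[:] = 0.0
        return eps
    eps[:, 0] = rng.normal(0.0, sigma, n_series)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        eps[:, j] = rho * eps[:, j - 1] + rng.normal(0.0, innov_sd, n_series)
    return eps


def synth_growth(cfg: SynthGrowthConfig):
    """Simulate a trait matrix from the functional ANOVA model.

    Returns ``(TraitMatrix, factors, truth)`` where ``truth`` maps
    ``"mu"``, ``"genotype"`` (list for levels 2..) and ``"block"`` to the
    true effect curves as callables.
    """
    rng = np.random.default_rng(cfg.seed)
    days = np.linspace(cfg.day_range[0], cfg.day_range[1], cfg.m_days)

    plant_rows = []
    values = []
    n_redrawn = 0
    for g in range(1, cfg.n_genotypes + 1):
        for b in range(1, cfg.n_blocks + 1):
            for r in range(1, cfg.n_replicates + 1):
                mean = np.asarray(cfg.mu(days), dtype=float).copy()
                if g > 1:
                    mean += cfg.genotype_effects[g - 2](days)
                if b > 1:
                    mean += cfg.block_effects[b - 2](days)
                eps = ar1_noise(rng, 1, cfg.m_days, cfg.sigma, cfg.rho)[0]
                keep = rng.random(cfg.m_days) < cfg.retention
                while not keep.any():
                    n_redrawn += 1
                    keep = rng.random(cfg.m_days) < cfg.retention
                row = np.where(keep, mean + eps, np.nan)
                values.append(row)
                plant_rows.append((f"g{g:03d}_b{b}_r{r}", f"g{g:03d}", f"b{b}"))
    if n_redrawn:
        warnings.warn(f"redrew the observation schedule of {n_redrawn} plant(s) "
                      "that retained no day", stacklevel=2)
    meta = pd.DataFrame(plant_rows, columns=["plant_id", "genotype", "block"])
    Y = TraitMatrix(np.asarray(values), days, meta, trait="size")
    truth = {"mu": cfg.mu, "genotype": list(cfg.genotype_effects), "block": list(cfg.block_effects)}
    return Y, meta, truth


@dataclass(frozen=True)
class CoverageResult:
    coverage: float
    per_t: np.ndarray
    tgrid: np.ndarray
    nreps: int
    n_failed: int
    level: float


def coverage_sim(
    cfg: SynthGrowthConfig,
    j1: int,
    j2: int,
    nreps: int,
    seed: int = 0,
    level: float = DEFAULT_LEVEL,
    formula: str = "size ~ genotype + block",
    lam_grid=None,
    n_interior: int | None = None,
) -> CoverageResult:
    """Monte-Carlo check of the pointwise band for a column contrast.

    For each replicate: simulate data, fit the model, build the band via
    :func:`ci_contrast`, and record at each union-grid day whether the true
    contrast curve lies inside the band.  Returns the mean pointwise coverage
    together with the per-day coverage profile.  Replicates whose fit fails
    are excluded with a warning and counted in ``n_failed``.
    """
    if nreps < 1:
        raise ValueError("nreps must be >= 1")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=nreps)

    hits = None
    n_failed = 0
    tgrid = None
    for s in rep_seeds:
        rep_cfg = replace(
            cfg,
            seed=int(s),
            mu=cfg.mu,
            genotype_effects=list(cfg.genotype_effects),
            block_effects=list(cfg.block_effects),
        )
        Y, factors, truth = synth_growth(rep_cfg)
        if tgrid is None:
            tgrid = Y.days
            hits = np.zeros((0, tgrid.size), dtype=bool)
        try:
            fit = fanova_fit(Y, formula, factors, lam_grid=lam_grid, n_interior=n_interior)
            band = ci_contrast(fit, j1, j2, level=level, tgrid=tgrid)
        except Exception as exc:  # noqa: BLE001 - a failed replicate is data, not a crash
            warnings.warn(f"replicate failed and was excluded: {exc}", stacklevel=2)
            n_failed += 1
            continue
        true_curve = _true_contrast(rep_cfg, j1, j2, tgrid)
        inside = (band.lower <= true_curve) & (true_curve <= band.upper)
        hits = np.vstack([hits, inside])
    if hits.shape[0] == 0:
        raise RuntimeError("all replicates failed")
    per_t = hits.mean(axis=0)
    return CoverageResult(float(hits.mean()), per_t, tgrid, hits.shape[0], n_failed, level)


def _true_contrast(cfg: SynthGrowthConfig, j1: int, j2: int, tgrid: np.ndarray) -> np.ndarray:
    """True curve of the e_{j1} - e_{j2} contrast under the generator's model
    (columns ordered intercept, genotype levels 2.., block levels 2..)."""

    def col_curve(j):
        if j == 1:
            return np.zeros(tgrid.size)  # baseline sentinel
        k = j - 2
        if k < cfg.n_genotypes - 1:
            return np.asarray(cfg.genotype_effects[k](tgrid), dtype=float)
        k -= cfg.n_genotypes - 1
        if k < cfg.n_blocks - 1:
            return np.asarray(cfg.block_effects[k](tgrid), dtype=float)
        raise ValueError(f"column index {j} out of range")

    return col_curve(j1) - col_curve(j2)


def significance_summary(band: CurveBand):
    """Maximal time intervals where the band excludes zero.

    Returns a list of ``(t_start, t_end, sign)`` tuples with sign ``+1``
    (lower limit above zero) or ``-1`` (upper limit below zero).
    """
    sign = np.zeros(band.tgrid.size, dtype=int)
    sign[band.lower > 0] = 1
    sign[band.upper < 0] = -1
    out = []
    start = None
    for i in range(sign.size + 1):
        s = sign[i] if i < sign.size else 0
        if start is not None and (s != sign[start]):
            out.append((float(band.tgrid[start]), float(band.tgrid[i - 1]), int(sign[start])))
            start = None
        if s != 0 and start is None:
            start = i
    return out
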