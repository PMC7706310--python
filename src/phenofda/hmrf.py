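"""Hidden Markov random field segmentation fitted by EM with ICM label updates.

The label field follows a Potts (Gibbs) prior in which each pair of unequal
neighboring labels costs ``beta``; given its label, a pixel's relative green
intensity is Gaussian with class-specific mean and variance.  Unlike simple
thresholding or K-means, the prior lets a pixel borrow class information from
its neighborhood, which fills in missing plant pixels and removes isolated
background noise.

Labels are integers ``0 .. K-1``; after fitting, the plant class is the one
with the larger mean relative green intensity (the class of highest index
after sorting by mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage
from sklearn.cluster import KMeans

__all__ = [
    "GaussParams",
    "HMRFConfig",
    "ClassCollapseError",
    "kmeans_labels",
    "hmrf_energy",
    "icm_sweep",
    "class_posteriors",
    "em_update_params",
    "hmrf_segment",
    "plant_class_mask",
]

_VAR_FLOOR = 1e-8


class ClassCollapseError(RuntimeError):
    """A class received (numerically) zero posterior mass during EM."""


@dataclass(frozen=True)
class GaussParams:
    """Per-class Gaussian emission parameters (means and variances)."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "var", np.asarray(self.var, dtype=np.float64))
        if self.mean.shape != self.var.shape or self.mean.ndim != 1:
            raise ValueError("mean and var must be 1-D arrays of equal length")
        if np.any(self.var <= 0):
            raise ValueError("variances must be positive")


@dataclass(frozen=True)
class HMRFConfig:
    K: int = 2
    beta: float = 1.0
    neighborhood: int = 4
    max_em_iter: int = 20
    max_icm_sweeps: int = 5
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.K < 2:
            raise ValueError("need at least 2 classes")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        if self.max_em_iter < 1 or self.max_icm_sweeps < 1:
            raise ValueError("iteration caps must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def _neighbor_kernel(neighborhood: int) -> np.ndarray:
    k = np.zeros((3, 3), dtype=np.float64)
    k[0, 1] = k[2, 1] = k[1, 0] = k[1, 2] = 1.0
    if neighborhood == 8:
        k[0, 0] = k[0, 2] = k[2, 0] = k[2, 2] = 1.0
    return k


def kmeans_labels(y: np.ndarray, K: int = 2, seed: int = 0) -> np.ndarray:
    """Initial labeling by Lloyd's algorithm on the scalar intensities.

    Centers start at K equally spaced quantiles of the intensity values, so
    the result is deterministic; labels are renumbered so class means
    increase with the label index.
    """
    y = np.asarray(y, dtype=np.float64)
    vals = y.ravel()
    uniq = np.unique(vals)
    if uniq.size < K:
        raise ValueError(f"need at least {K} distinct intensity values, got {uniq.size}")
    centers = np.quantile(vals, (np.arange(K) + 0.5) / K)
    if np.unique(centers).size < K:
        idx = np.round(np.linspace(0, uniq.size - 1, K)).astype(int)
        centers = uniq[idx]
    km = KMeans(n_clusters=K, init=centers.reshape(-1, 1), n_init=1, random_state=seed)
    flat = km.fit_predict(vals.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    relabel = np.empty(K, dtype=np.int64)
    relabel[order] = np.arange(K)
    return relabel[flat].reshape(y.shape)


def _check_labels(x: np.ndarray, K: int) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError("label map must be 2-D")
    if x.min() < 0 or x.max() >= K:
        raise ValueError(f"labels must lie in 0..{K - 1}")
    return x.astype(np.int64)


def _gauss_neglog(y: np.ndarray, params: GaussParams) -> np.ndarray:
    """(H, W, K) array of Gaussian negative log-densities."""
    y = y[..., None]
    mu = params.mean[None, None, :]
    var = params.var[None, None, :]
    return 0.5 * ((y - mu) ** 2 / var + np.log(2.0 * np.pi * var))


def hmrf_energy(x: np.ndarray, y: np.ndarray, params: GaussParams, cfg: HMRFConfig) -> float:
    """Negative log joint (up to a constant): Gaussian data term plus
    ``beta`` times the number of unequal unordered neighbor pairs."""
    x = _check_labels(x, cfg.K)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("label and intensity shapes differ")
    g = _gauss_neglog(y, params)
    data = np.take_along_axis(g, x[..., None], axis=2).sum()
    pairs = np.sum(x[:, :-1] != x[:, 1:]) + np.sum(x[:-1, :] != x[1:, :])
    if cfg.neighborhood == 8:
        pairs += np.sum(x[:-1, :-1] != x[1:, 1:]) + np.sum(x[:-1, 1:] != x[1:, :-1])
    return float(data + cfg.beta * pairs)


@njit(cache=False)
def _sweep(x, y, mu, var, beta, eight):  # pragma: no cover - compiled
    H, W = x.shape
    K = mu.shape[0]
    changes = 0
    for r in range(H):
        for c in range(W):
            cur = x[r, c]
            best_k = 0
            best_e = 1e300
            cur_e = 1e300
            for k in range(K):
                e = 0.5 * ((y[r, c] - mu[k]) ** 2 / var[k] + np.log(2.0 * np.pi * var[k]))
                d = 0
                if r > 0 and x[r - 1, c] != k:
                    d += 1
                if r < H - 1 and x[r + 1, c] != k:
                    d += 1
                if c > 0 and x[r, c - 1] != k:
                    d += 1
                if c < W - 1 and x[r, c + 1] != k:
                    d += 1
                if eight:
                    if r > 0 and c > 0 and x[r - 1, c - 1] != k:
                        d += 1
                    if r > 0 and c < W - 1 and x[r - 1, c + 1] != k:
                        d += 1
                    if r < H - 1 and c > 0 and x[r + 1, c - 1] != k:
                        d += 1
                    if r < H - 1 and c < W - 1 and x[r + 1, c + 1] != k:
                        d += 1
                e += beta * d
                if k == cur:
                    cur_e = e
                if e < best_e:
                    best_e = e
                    best_k = k
            # switch only on a strict improvement: the current label wins
            # ties, so a full sweep can never increase the total energy
            if best_e < cur_e:
                x[r, c] = best_k
                changes += 1
    return changes


def icm_sweep(x: np.ndarray, y: np.ndarray, params: GaussParams, cfg: HMRFConfig) -> np.ndarray:
    """One raster-order ICM pass: each pixel takes the label minimizing its
    local conditional energy given the current neighbor labels (ties keep the
    current label, so the total energy never increases)."""
    x = _check_labels(x, cfg.K).copy()
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("label and intensity shapes differ")
    _sweep(x, y, params.mean, params.var, float(cfg.beta), cfg.neighborhood == 8)
    return x


def class_posteriors(x: np.ndarray, y: np.ndarray, params: GaussParams, cfg: HMRFConfig) -> np.ndarray:
    """Pixelwise class posteriors proportional to exp(-local energy), with the
    Potts term evaluated against the current neighbor labels."""
    x = _check_labels(x, cfg.K)
    y = np.asarray(y, dtype=np.float64)
    kernel = _neighbor_kernel(cfg.neighborhood)
    n_nb = ndimage.correlate(np.ones_like(y), kernel, mode="constant", cval=0.0)
    energy = _gauss_neglog(y, params)
    for k in range(cfg.K):
        eq = ndimage.correlate((x == k).astype(np.float64), kernel, mode="constant", cval=0.0)
        energy[:, :, k] += cfg.beta * (n_nb - eq)
    energy -= energy.min(axis=2, keepdims=True)
    p = np.exp(-energy)
    p /= p.sum(axis=2, keepdims=True)
    return p


def em_update_params(y: np.ndarray, p: np.ndarray) -> GaussParams:
    """Posterior-weighted ML update of the class means and variances.

    Variances are floored at 1e-8 so near-constant regions cannot produce a
    singular Gaussian.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if p.shape[:2] != y.shape:
        raise ValueError("posterior and intensity shapes differ")
    mass = p.sum(axis=(0, 1))
    if np.any(mass <= 1e-12):
        raise ClassCollapseError(f"class with zero posterior mass (masses: {mass})")
    mu = np.tensordot(p, y, axes=((0, 1), (0, 1))) / mass
    dev2 = (y[..., None] - mu[None, None, :]) ** 2
    var = (p * dev2).sum(axis=(0, 1)) / mass
    return GaussParams(mu, np.maximum(var, _VAR_FLOOR))


def _onehot(x: np.ndarray, K: int) -> np.ndarray:
    p = np.zeros(x.shape + (K,), dtype=np.float64)
    np.put_along_axis(p, x[..., None], 1.0, axis=2)
    return p


def hmrf_segment(y: np.ndarray, init: np.ndarray, cfg: HMRFConfig = HMRFConfig()):
    """Fit the HMRF by EM and return ``(labels, params, posteriors)``.

    Alternates ICM label sweeps (given the current Gaussian parameters) with
    posterior-weighted parameter updates, stopping when the relative change
    of all means and variances drops below ``cfg.tol`` or after
    ``cfg.max_em_iter`` outer iterations.  Deterministic: fixed raster order,
    fixed initialization.
    """
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    labels = _check_labels(init, cfg.K).copy()
    params = em_update_params(y, _onehot(labels, cfg.K))

    for _ in range(cfg.max_em_iter):
        for _ in range(cfg.max_icm_sweeps):
            changes = _sweep(labels, y, params.mean, params.var, float(cfg.beta), cfg.neighborhood == 8)
            if changes == 0:
                break
        post = class_posteriors(labels, y, params, cfg)
        new = em_update_params(y, post)
        denom = np.maximum(np.abs(params.mean), 1e-12)
        rel = np.max(np.abs(new.mean - params.mean) / denom)
        rel = max(rel, np.max(np.abs(new.var - params.var) / np.maximum(params.var, 1e-12)))
        params = new
        if rel < cfg.tol:
            break
    # final label update so the returned labels are MAP-style under the
    # returned (converged) parameters
    for _ in range(cfg.max_icm_sweeps):
        if _sweep(labels, y, params.mean, params.var, float(cfg.beta), cfg.neighborhood == 8) == 0:
            break
    post = class_posteriors(labels, y, params, cfg)
    return labels, params, post


def plant_class_mask(labels: np.ndarray, params: GaussParams) -> np.ndarray:
    """Boolean plant mask: the class with the largest mean intensity."""
    return np.asarray(labels) == int(np.argmax(params.mean))
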