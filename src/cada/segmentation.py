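"""Unsupervised striatal segmentation with a two-component 4-D Gaussian mixture.

Every brain voxel is a 4-vector x = (intensity, i, j, k).  Per hemisphere,
a two-component full-covariance Gaussian mixture

    p(x | λ) = Σ_i ω_i N(x | μ_i, Σ_i),   Σ ω_i = 1,

is fitted by expectation-maximization, and each voxel is assigned to the
component maximizing the unweighted, normalized component likelihood

    exp(−½ (x−μ_i)ᵀ Σ_i⁻¹ (x−μ_i)) / |Σ_i|^{1/2},

with ties broken toward the lower component index.  The component with the
larger mean intensity is the striatum; its largest 26-connected component
becomes that side's binary mask.  MAP labeling (mixture weights included)
is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from cada.errors import EmptySegmentationError, SampleSizeError
from cada.preprocess import brain_mask
from cada.volume_io import Mask, Volume, lr_axis

__all__ = [
    "GmmModel",
    "SegmentationResult",
    "gmm_density",
    "fit_gmm_em",
    "label_voxels",
    "segment_striata",
]

_RIDGE_COND = 1e10
_RIDGE_EPS = 1e-6


@dataclass
class GmmModel:
    """λ = {ω_i, μ_i, Σ_i}: weights, 4-D means, full covariances."""

    weights: np.ndarray
    means: np.ndarray        # (M, d)
    covariances: np.ndarray  # (M, d, d)
    loglik_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1, got {self.weights.sum()}")
        for S in self.covariances:
            if np.linalg.eigvalsh(S)[0] <= 0:
                raise np.linalg.LinAlgError("covariance not positive definite")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> int:
        return self.means.shape[1]


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log multivariate normal density, row-wise."""
    d = mean.size
    L = np.linalg.cholesky(cov)
    z = np.linalg.solve(L, (x - mean).T)
    maha = np.sum(z * z, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def gmm_density(x: np.ndarray, model: GmmModel) -> np.ndarray:
    """Mixture density Σ ω_i N(x | μ_i, Σ_i) at each row of x."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    logs = np.stack([
        np.log(model.weights[i]) + _log_gauss(x, model.means[i],
                                              model.covariances[i])
        for i in range(model.n_components)
    ])
    m = logs.max(axis=0)
    return np.exp(m) * np.sum(np.exp(logs - m), axis=0)


def _kmeans_init(x: np.ndarray, M: int, rng: np.random.Generator,
                 n_iter: int = 10) -> np.ndarray:
    """k-means++ seeding plus a short Lloyd refinement; returns hard labels."""
    n = x.shape[0]
    centers = np.empty((M, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = np.sum((x - centers[0]) ** 2, axis=1)
    for i in range(1, M):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[i] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((x - centers[i]) ** 2, axis=1))
    for _ in range(n_iter):
        dist = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = dist.argmin(axis=1)
        for i in range(M):
            sel = labels == i
            if sel.any():
                centers[i] = x[sel].mean(axis=0)
    dist = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return dist.argmin(axis=1)


def _m_step(x: np.ndarray, resp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = x.shape
    nk = resp.sum(axis=0) + 1e-12
    weights = nk / n
    means = (resp.T @ x) / nk[:, None]
    covs = np.empty((resp.shape[1], d, d))
    for i in range(resp.shape[1]):
        dx = x - means[i]
        covs[i] = (resp[:, i][:, None] * dx).T @ dx / nk[i]
        # ridge regularization against component collapse
        ev = np.linalg.eigvalsh(covs[i])
        if ev[0] <= 0 or ev[-1] / max(ev[0], 1e-300) > _RIDGE_COND:
            ridge = _RIDGE_EPS * np.trace(covs[i]) / d + 1e-12
            covs[i] += ridge * np.eye(d)
            warnings.warn(
                f"component {i} covariance near-singular; ridge {ridge:.3g} added",
                RuntimeWarning, stacklevel=3,
            )
    return weights, means, covs


def fit_gmm_em(features: np.ndarray, M: int = 2, seed: int = 17, *,
               tol: float = 1e-6, max_iter: int = 500,
               init: str = "kmeans") -> GmmModel:
    """Fit an M-component full-covariance Gaussian mixture by EM.

    ``init="kmeans"`` seeds components with k-means++ (plus a short Lloyd
    refinement) on the raw features, driven entirely by ``seed``.
    ``init="intensity"`` (M = 2 only) seeds from a quantile split on the
    first feature axis; with spatial coordinates in the feature vector this
    steers EM to the uptake-relevant local maximum rather than a purely
    spatial partition of the brain.  The log-likelihood is non-decreasing
    across iterations; convergence is declared when its relative change
    drops below ``tol``.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n, d = x.shape
    if n <= 10 * M * d:
        raise SampleSizeError(f"need > {10 * M * d} samples for M={M}, d={d}; got {n}")
    rng = np.random.default_rng(seed)
    resp = np.zeros((n, M))
    if init == "intensity":
        if M != 2:
            raise ValueError("intensity initialization requires M = 2")
        hot = x[:, 0] > np.quantile(x[:, 0], 0.995)
        if not hot.any() or hot.all():
            raise SampleSizeError("intensity split degenerate")
        resp[:, 1] = hot
        resp[:, 0] = ~hot
    elif init == "kmeans":
        labels = _kmeans_init(x, M, rng)
        resp[np.arange(n), labels] = 1.0
    else:
        raise ValueError(f"unknown init {init!r}")
    weights, means, covs = _m_step(x, resp)

    history: list[float] = []
    for _ in range(max_iter):
        logs = np.stack([
            np.log(weights[i]) + _log_gauss(x, means[i], covs[i])
            for i in range(M)
        ], axis=1)
        m = logs.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.sum(np.exp(logs - m), axis=1))
        ll = float(lse.sum())
        history.append(ll)
        if len(history) > 1:
            prev = history[-2]
            if abs(ll - prev) <= tol * abs(prev):
                break
        resp = np.exp(logs - lse[:, None])
        weights, means, covs = _m_step(x, resp)
    weights = weights / weights.sum()
    return GmmModel(weights, means, covs, loglik_history=history)


def label_voxels(features: np.ndarray, model: GmmModel, *,
                 use_weights: bool = False) -> np.ndarray:
    """Maximum-likelihood component labels.

    The score is the unweighted normalized component likelihood
    exp(−½ maha)/|Σ|^{1/2} (the shared (2π)^{d/2} factor cancels in the
    argmax); ``use_weights=True`` switches to MAP labeling with ω_i.
    Ties resolve to the lower component index.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    scores = np.empty((x.shape[0], model.n_components))
    for i in range(model.n_components):
        L = np.linalg.cholesky(model.covariances[i])
        z = np.linalg.solve(L, (x - model.means[i]).T)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        scores[:, i] = -0.5 * np.sum(z * z, axis=0) - 0.5 * logdet
        if use_weights:
            scores[:, i] += np.log(model.weights[i])
    return scores.argmax(axis=1)


@dataclass
class SegmentationResult:
    left: Mask
    right: Mask
    model_left: GmmModel
    model_right: GmmModel
    loglik: dict[str, float]


def _voxel_features(v: Volume, sel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coords = np.argwhere(sel)
    intens = v.data[sel]
    return np.column_stack([intens, coords.astype(float)]), coords


def _largest_cc(binary: np.ndarray) -> np.ndarray:
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return binary
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled,
                               index=np.arange(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def segment_striata(v: Volume, template: Volume, seed: int = 17, *,
                    use_weights: bool = False,
                    mask_fraction: float = 0.05) -> SegmentationResult:
    """Segment the left and right striatum of a registered volume.

    The brain is split at the template mid-plane; per hemisphere a
    2-component GMM on (intensity, i, j, k) features of brain-mask voxels is
    fitted by EM, voxels are ML-labeled, the component with the larger mean
    intensity is taken as striatum, and its largest 26-connected component
    becomes the side's mask.
    """
    # exclude the partial-volume rim of the brain: keep voxels above half the
    # median in-brain template intensity, else the mixture splits rim vs
    # interior instead of background vs striatum
    rough = brain_mask(template, fraction=mask_fraction).data
    bm = rough & (template.data > 0.5 * np.median(template.data[rough]))
    axis = lr_axis(template.affine)
    mid = v.shape[axis] // 2
    sl_left = [slice(None)] * 3
    sl_left[axis] = slice(0, mid)
    sl_right = [slice(None)] * 3
    sl_right[axis] = slice(mid, None)

    sides: dict[str, Mask] = {}
    models: dict[str, GmmModel] = {}
    logliks: dict[str, float] = {}
    for side, sl in (("left", tuple(sl_left)), ("right", tuple(sl_right))):
        hemi = np.zeros(v.shape, dtype=bool)
        hemi[sl] = True
        sel = bm & hemi
        if sel.sum() <= 80:
            raise EmptySegmentationError(side, f"hemisphere {side} brain mask "
                                               f"holds only {int(sel.sum())} voxels")
        feats, coords = _voxel_features(v, sel)
        model = fit_gmm_em(feats, M=2, seed=seed, init="intensity")
        labels = label_voxels(feats, model, use_weights=use_weights)
        striatal_comp = int(np.argmax(model.means[:, 0]))
        hot = labels == striatal_comp
        if not hot.any():
            raise EmptySegmentationError(side)
        binary = np.zeros(v.shape, dtype=bool)
        binary[tuple(coords[hot].T)] = True
        binary = _largest_cc(binary)
        if not binary.any():
            raise EmptySegmentationError(side)
        sides[side] = Mask(binary, side=side)
        models[side] = model
        logliks[side] = model.loglik_history[-1] if model.loglik_history else float("nan")

    return SegmentationResult(
        left=sides["left"], right=sides["right"],
        model_left=models["left"], model_right=models["right"],
        loglik=logliks,
    )
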