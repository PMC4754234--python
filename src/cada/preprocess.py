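"""Spatial and intensity normalization.

Spatial normalization registers every subject to a symmetric template built
from the control group with a 6-degree-of-freedom rigid transform (the
pipeline needs a common overall position, not voxel-perfect warping).
Intensity normalization models the brain intensity histogram as a positively
skewed α-stable distribution and applies, per image, the linear map that
sends the fitted dispersion/location (γ_i, μ_i) to the pooled values
(γ*, μ*):

    Y = a_i X − b_i,   a_i = γ*/γ_i,   b_i = a_i μ_i − μ*.

α-stable parameters are estimated with a McCulloch-style quantile method:
sample quantiles are matched against a precomputed grid of standard stable
quantiles (S0 parameterization), which is closed-form fast and fully
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.transform import Rotation

from cada import _stable_tables as _tab
from cada.errors import DegenerateInputError, InsufficientInputError, SampleSizeError
from cada.volume_io import Mask, Volume, reflect_midplane

__all__ = [
    "RigidTransform",
    "AlphaStableParams",
    "NormalizationModel",
    "register_rigid",
    "build_template",
    "brain_mask",
    "fit_alpha_stable",
    "fit_alpha_stable_sample",
    "normalize_intensity",
]


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Proper rigid motion: axis-angle rotation (rad) + translation (mm).

    The transform acts in world coordinates about a fixed centre point:
    ``p -> R (p - c) + c + t``.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def matrix(self, center: np.ndarray) -> np.ndarray:
        """4x4 homogeneous world-space matrix about ``center``."""
        R = Rotation.from_rotvec(self.rotation).as_matrix()
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = center - R @ center + self.translation
        return T


def _world_center(v: Volume) -> np.ndarray:
    idx = (np.asarray(v.shape, dtype=float) - 1.0) / 2.0
    return (v.affine @ np.append(idx, 1.0))[:3]


def _resample_onto(moving: Volume, fixed: Volume, transform: RigidTransform,
                   center: np.ndarray) -> np.ndarray:
    """Resample ``moving`` on the grid of ``fixed`` under ``transform``.

    Trilinear interpolation; out-of-field voxels are 0.
    """
    M = np.linalg.inv(moving.affine) @ transform.matrix(center) @ fixed.affine
    return ndimage.affine_transform(
        moving.data, M[:3, :3], offset=M[:3, 3],
        output_shape=fixed.shape, order=1, mode="constant", cval=0.0,
    )


def _downsample(v: Volume, factor: int) -> Volume:
    """Block-mean downsampling with an affine that keeps world coordinates."""
    if factor == 1:
        return v
    shape = tuple((s // factor) * factor for s in v.shape)
    if min(shape) == 0:
        return v
    d = v.data[: shape[0], : shape[1], : shape[2]]
    d = d.reshape(shape[0] // factor, factor, shape[1] // factor, factor,
                  shape[2] // factor, factor).mean(axis=(1, 3, 5))
    S = np.eye(4)
    S[:3, :3] *= factor
    S[:3, 3] = (factor - 1) / 2.0
    return Volume(d, tuple(s * factor for s in v.spacing), v.affine @ S, v.id)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def register_rigid(moving: Volume, fixed: Volume, *,
                   levels: tuple[int, ...] = (4, 2, 1),
                   max_iter: int = 40) -> tuple[RigidTransform, Volume]:
    """6-DOF registration maximizing normalized correlation.

    Multi-resolution (coarse-to-fine block means) with a derivative-free
    Powell search started at the identity, hence fully deterministic.

    Returns the transform and the moving volume resampled on the fixed grid.
    """
    if float(np.std(moving.data)) == 0 or float(np.std(fixed.data)) == 0:
        raise DegenerateInputError("cannot register a constant image")
    center = _world_center(fixed)
    x = np.zeros(6)
    # angles scaled so one unit step ~ 1 voxel of motion at the brain radius
    scale = np.array([0.02, 0.02, 0.02, 1.0, 1.0, 1.0])

    for factor in sorted(set(levels), reverse=True):
        fx = _downsample(fixed, factor)
        mv = _downsample(moving, factor)

        def objective(u: np.ndarray) -> float:
            t = RigidTransform(u[:3] * scale[:3], u[3:] * scale[3:])
            return -_ncc(_resample_onto(mv, fx, t, center), fx.data)

        res = optimize.minimize(
            objective, x, method="Powell",
            options={"maxiter": max_iter, "xtol": 1e-3, "ftol": 1e-7},
        )
        if not res.success and "maximum" in str(res.message).lower():
            warnings.warn(
                f"registration did not converge at level {factor}: {res.message}",
                RuntimeWarning, stacklevel=2,
            )
        x = res.x
    transform = RigidTransform(x[:3] * scale[:3], x[3:] * scale[3:])
    resampled = fixed.copy_with(
        _resample_onto(moving, fixed, transform, center), id=moving.id
    )
    return transform, resampled


def build_template(controls: list[Volume], *, n_refine: int = 2,
                   levels: tuple[int, ...] = (4, 2, 1),
                   max_iter: int = 40) -> Volume:
    """Average co-registered controls into a mid-plane-symmetric template.

    Controls are registered to a running mean (``n_refine`` rounds), averaged,
    and the result is symmetrized as (T + reflect(T))/2, which is exactly
    invariant under mid-plane reflection.
    """
    if len(controls) < 2:
        raise InsufficientInputError(
            f"template build needs >= 2 controls, got {len(controls)}"
        )
    ref = controls[0].copy_with(
        np.mean([c.data for c in controls], axis=0), id="template"
    )
    for _ in range(n_refine):
        resampled = [
            register_rigid(c, ref, levels=levels, max_iter=max_iter)[1]
            for c in controls
        ]
        ref = ref.copy_with(np.mean([r.data for r in resampled], axis=0))
    sym = (ref.data + reflect_midplane(ref).data) / 2.0
    return ref.copy_with(sym, id="template")


# ---------------------------------------------------------------------------
# alpha-stable intensity normalization
# ---------------------------------------------------------------------------

@dataclass
class AlphaStableParams:
    """Fitted skewed-stable parameters (S0 parameterization).

    alpha: stability exponent in (0, 2]; beta: skewness in [-1, 1];
    gamma: dispersion > 0 (for alpha=2, gamma = sigma/sqrt(2));
    mu: location in intensity units.
    """

    alpha: float
    beta: float
    gamma: float
    mu: float

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 2):
            raise ValueError(f"alpha must be in (0, 2], got {self.alpha}")
        if not (-1 <= self.beta <= 1):
            raise ValueError(f"beta must be in [-1, 1], got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


def _interpolators():
    """Quantile surfaces q_p(alpha, beta) extended to beta < 0 by mirror symmetry."""
    alphas = _tab.ALPHA_GRID
    betas_pos = _tab.BETA_GRID
    q = _tab.QUANTILES  # (n_alpha, n_beta, 5)
    betas = np.concatenate([-betas_pos[:0:-1], betas_pos])
    # q_p(alpha, -beta) = -q_{1-p}(alpha, beta); PROBS are symmetric about 0.5
    q_neg = -q[:, :0:-1, ::-1]
    full = np.concatenate([q_neg, q], axis=1)
    return [
        RegularGridInterpolator((alphas, betas), full[:, :, k],
                                bounds_error=False, fill_value=None)
        for k in range(5)
    ]


_QUANTILE_FNS = _interpolators()


def _standard_quantiles(alpha: float, beta: float) -> np.ndarray:
    pt = np.array([[alpha, beta]])
    return np.array([fn(pt)[0] for fn in _QUANTILE_FNS])


def fit_alpha_stable_sample(x: np.ndarray) -> AlphaStableParams:
    """Quantile-matching stable fit of a 1-D sample.

    The spread ratio ν_α = (x95−x05)/(x75−x25) and skew ratio
    ν_β = (x95+x05−2·x50)/(x95−x05) are location/scale free; (α, β) are found
    by matching them on the standard-quantile grid, then γ scales the
    interquartile range and μ shifts the median.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 500:
        raise SampleSizeError(f"need >= 500 samples, got {x.size}")
    q = np.quantile(x, _tab.PROBS)
    iqr = q[3] - q[1]
    if iqr <= 0 or q[4] - q[0] <= 0:
        raise DegenerateInputError("zero-variance sample")
    nu_a = (q[4] - q[0]) / iqr
    nu_b = (q[4] + q[0] - 2 * q[2]) / (q[4] - q[0])

    def resid(p: np.ndarray) -> np.ndarray:
        sq = _standard_quantiles(p[0], p[1])
        m_a = (sq[4] - sq[0]) / (sq[3] - sq[1])
        m_b = (sq[4] + sq[0] - 2 * sq[2]) / (sq[4] - sq[0])
        return np.array([m_a - nu_a, 3.0 * (m_b - nu_b)])

    sol = optimize.least_squares(
        resid, x0=np.array([1.6, 0.0]),
        bounds=([_tab.ALPHA_GRID[0], -1.0], [2.0, 1.0]),
        xtol=1e-10, ftol=1e-12,
    )
    alpha, beta = float(sol.x[0]), float(sol.x[1])
    if alpha > 1.99:
        # skewness is unidentifiable at the Gaussian boundary
        beta = 0.0
    sq = _standard_quantiles(alpha, beta)
    gamma = iqr / (sq[3] - sq[1])
    mu = q[2] - gamma * sq[2]
    return AlphaStableParams(alpha=alpha, beta=beta, gamma=float(gamma),
                             mu=float(mu))


def brain_mask(v: Volume, fraction: float = 0.05) -> Mask:
    """Voxels above ``fraction`` of the robust intensity range.

    The threshold is anchored between the 1st and 99.5th percentiles,
    q01 + fraction*(q995 - q01), which on a raw volume (air at 0) reduces to
    a fraction of the robust maximum while staying exactly equivariant under
    the linear intensity normalization: the mask of a normalized volume
    equals the mask of its input.
    """
    q01, q995 = np.percentile(v.data, [1.0, 99.5])
    level = q01 + fraction * (q995 - q01)
    return Mask(v.data > level)


def fit_alpha_stable(v: Volume, mask: Mask | None = None) -> AlphaStableParams:
    """Fit the stable law to the in-mask intensity sample of a volume."""
    if mask is None:
        mask = brain_mask(v)
    sample = v.data[mask.data]
    if sample.size < 500:
        raise SampleSizeError(
            f"brain mask of {v.id!r} holds {sample.size} voxels; need >= 500"
        )
    return fit_alpha_stable_sample(sample)


@dataclass
class NormalizationModel:
    """Pooled dispersion/location targets and per-image linear coefficients."""

    gamma_star: float
    mu_star: float
    per_image: list[tuple[str, float, float]]  # (id, a_i, b_i)

    def to_dict(self) -> dict:
        return {
            "gamma_star": self.gamma_star,
            "mu_star": self.mu_star,
            "per_image": [
                {"id": i, "a": a, "b": b} for i, a, b in self.per_image
            ],
        }


def normalize_intensity(
    volumes: list[Volume], masks: list[Mask] | None = None,
) -> tuple[NormalizationModel, list[Volume]]:
    """Linear intensity normalization via per-image stable fits.

    Each image is mapped by Y = a_i X − b_i with a_i = γ*/γ_i and
    b_i = a_i μ_i − μ*, where γ*/μ* are the means of the per-image fits; the
    map sends every fitted (γ_i, μ_i) to the pooled target exactly, so
    normalizing already-normalized data is the identity up to estimator noise.
    """
    if masks is None:
        masks = [brain_mask(v) for v in volumes]
    fits = []
    for v, m in zip(volumes, masks):
        try:
            fits.append(fit_alpha_stable(v, m))
        except Exception as exc:
            raise type(exc)(f"stable fit failed for image {v.id!r}: {exc}") from exc
    gamma_star = float(np.mean([f.gamma for f in fits]))
    mu_star = float(np.mean([f.mu for f in fits]))
    per_image: list[tuple[str, float, float]] = []
    out: list[Volume] = []
    for v, f in zip(volumes, fits):
        a = gamma_star / f.gamma
        b = a * f.mu - mu_star
        per_image.append((v.id, float(a), float(b)))
        out.append(v.copy_with(a * v.data - b))
    return NormalizationModel(gamma_star, mu_star, per_image), out
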