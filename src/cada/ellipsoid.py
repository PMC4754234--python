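"""Ellipsoid shape modelling of striatal masks.

Each segmented striatum is summarized by the ellipsoid
``(X - U)^T R^T D R (X - U) = 1`` (centre U, row-eigenvector orientation R,
D = diag(1/axis^2)) that minimizes the summed squared Euclidean distances
from the mask's surface voxels to the ellipsoid surface.  The orientation
eigenvectors, paired by semi-axis rank, feed the dysmorphic index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from cada.errors import DegeneracyError, EmptyROIError
from cada.volume_io import Mask, Volume

__all__ = [
    "Ellipsoid",
    "FitReport",
    "mask_surface_points",
    "point_ellipsoid_distance",
    "fit_ellipsoid",
    "ellipsoid_roi",
]


@dataclass
class Ellipsoid:
    """Ellipsoid with centre, orthonormal orientation and semi-axis lengths.

    ``orientation`` rows are unit eigenvectors ordered by descending
    semi-axis length; ``semi_axes`` is stored descending.  The canonical
    representative fixes the sign of the first two rows (largest-magnitude
    entry positive) and sets the third to their cross product, so
    det(orientation) = +1.
    """

    center: np.ndarray
    orientation: np.ndarray
    semi_axes: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float).reshape(3)
        if np.any(self.semi_axes <= 0):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        if not np.allclose(self.orientation @ self.orientation.T, np.eye(3),
                           atol=1e-8):
            raise ValueError("orientation must be orthonormal")
        self._canonicalize()

    def _canonicalize(self) -> None:
        order = np.argsort(-self.semi_axes, kind="stable")
        self.semi_axes = self.semi_axes[order]
        R = self.orientation[order]
        for i in range(2):
            j = np.argmax(np.abs(R[i]))
            if R[i, j] < 0:
                R[i] = -R[i]
        R[2] = np.cross(R[0], R[1])
        self.orientation = R

    def to_principal(self, points: np.ndarray) -> np.ndarray:
        """Map world points into the principal (axis-aligned) frame."""
        return (np.atleast_2d(points) - self.center) @ self.orientation.T

    def quadratic_form(self, points: np.ndarray) -> np.ndarray:
        """(X-U)^T R^T D R (X-U) for each point; 1 on the surface."""
        y = self.to_principal(points) / self.semi_axes
        return np.einsum("ij,ij->i", y, y)

    def to_dict(self, energy: float | None = None) -> dict:
        out = {
            "center": self.center.tolist(),
            "rotation_matrix": self.orientation.tolist(),
            "semi_axes": self.semi_axes.tolist(),
        }
        if energy is not None:
            out["energy"] = float(energy)
        return out


@dataclass
class FitReport:
    final_energy: float
    n_points: int
    iterations: int
    converged: bool
    initial_energy: float = float("nan")


def mask_surface_points(m: Mask) -> np.ndarray:
    """Coordinates of mask voxels with at least one 6-connected background
    neighbour (grid boundary counts as background)."""
    if m.is_empty():
        raise EmptyROIError("empty mask has no surface")
    interior = ndimage.binary_erosion(
        m.data, structure=ndimage.generate_binary_structure(3, 1),
        border_value=0,
    )
    surface = m.data & ~interior
    return np.argwhere(surface).astype(float)


def _principal_distances(y: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Distances from points ``y`` (principal frame) to the axis-aligned
    ellipsoid surface.

    Solves, per point, the Lagrange condition for the closest surface point:
    the root t of F(t) = sum_i (a_i y_i / (t + a_i^2))^2 - 1 on
    (-a_min^2, inf), by vectorized bracketing bisection.  Exactly-zero
    components are nudged by a negligible epsilon; the distance function is
    1-Lipschitz in the point so the induced error is of the same order.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    a = np.asarray(axes, dtype=float)
    a2 = a * a
    eps = 1e-9 * a.min()
    ysafe = np.where(np.abs(y) < eps, eps, y)

    def F(t: np.ndarray) -> np.ndarray:
        denom = t[:, None] + a2[None, :]
        return np.sum((a[None, :] * ysafe / denom) ** 2, axis=1) - 1.0

    n = ysafe.shape[0]
    lo = np.full(n, -a2.min() * (1 - 1e-12))
    hi = np.maximum(a.max() * np.linalg.norm(ysafe, axis=1), a.max())
    # expand upper bracket until F(hi) < 0
    for _ in range(100):
        bad = F(hi) > 0
        if not bad.any():
            break
        hi[bad] *= 2.0
    with np.errstate(over="ignore", divide="ignore"):
        for _ in range(120):
            mid = 0.5 * (lo + hi)
            pos = F(mid) > 0
            lo = np.where(pos, mid, lo)
            hi = np.where(pos, hi, mid)
    t = 0.5 * (lo + hi)
    closest = a2[None, :] * ysafe / (t[:, None] + a2[None, :])
    return np.linalg.norm(y - closest, axis=1)


def point_ellipsoid_distance(p: np.ndarray, e: Ellipsoid) -> float:
    """Euclidean distance from a point to the nearest ellipsoid surface point.

    The centre is handled exactly: its distance is the smallest semi-axis.
    """
    y = e.to_principal(np.asarray(p, dtype=float))[0]
    if np.linalg.norm(y) < 1e-12 * e.semi_axes.min():
        return float(e.semi_axes.min())
    return float(_principal_distances(y[None, :], e.semi_axes)[0])


def _distances(points: np.ndarray, center: np.ndarray, rotvec: np.ndarray,
               axes: np.ndarray) -> np.ndarray:
    R = Rotation.from_rotvec(rotvec).as_matrix()
    y = (points - center) @ R.T
    return _principal_distances(y, axes)


def fit_ellipsoid(points: np.ndarray) -> tuple[Ellipsoid, FitReport]:
    """Least-squares ellipsoid fit minimizing summed squared surface distances.

    Nonlinear least squares over centre, axis-angle rotation and
    log-semi-axes, started from a moment-based initializer (point centroid,
    covariance eigenvectors, covariance-shaped axes scaled to the RMS point
    radius).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if points.shape[0] < 10:
        raise DegeneracyError(
            f"need >= 10 points for an ellipsoid fit, got {points.shape[0]}"
        )
    c0 = points.mean(axis=0)
    cov = np.cov((points - c0).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-9 * max(evals[-1], 1e-30):
        raise DegeneracyError("points are coplanar or degenerate")
    order = np.argsort(-evals)
    dirs = evecs[:, order].T          # rows = principal directions, desc
    s = np.sqrt(2.0 * evals[order])
    y0 = (points - c0) @ dirs.T
    k = np.sqrt(np.mean(np.sum((y0 / s) ** 2, axis=1)))
    axes0 = np.maximum(k * s, 1e-3)
    if np.linalg.det(dirs) < 0:
        dirs[2] = -dirs[2]
    rot0 = Rotation.from_matrix(dirs).as_rotvec()

    def residuals(p: np.ndarray) -> np.ndarray:
        return _distances(points, p[:3], p[3:6], np.exp(p[6:9]))

    p0 = np.concatenate([c0, rot0, np.log(axes0)])
    e0 = float(np.sum(residuals(p0) ** 2))
    sol = optimize.least_squares(
        residuals, p0, method="lm", ftol=1e-10, xtol=1e-10, max_nfev=200 * 10,
    )
    energy = float(np.sum(sol.fun ** 2))
    if energy > e0:           # LM should never worsen the start, but be safe
        sol.x, energy = p0, e0
    ell = Ellipsoid(
        center=sol.x[:3],
        orientation=Rotation.from_rotvec(sol.x[3:6]).as_matrix(),
        semi_axes=np.exp(sol.x[6:9]),
    )
    report = FitReport(
        final_energy=energy, n_points=points.shape[0],
        iterations=int(sol.nfev), converged=bool(sol.status > 0),
        initial_energy=e0,
    )
    return ell, report


def ellipsoid_roi(e: Ellipsoid, grid: Volume) -> Mask:
    """Mask of grid voxels whose centres lie inside the ellipsoid."""
    shape = grid.shape
    lo = np.maximum(np.floor(e.center - e.semi_axes.max() - 1), 0).astype(int)
    hi = np.minimum(np.ceil(e.center + e.semi_axes.max() + 2),
                    np.asarray(shape)).astype(int)
    out = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        raise EmptyROIError("ellipsoid lies outside the grid")
    ii, jj, kk = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)],
                             indexing="ij")
    pts = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    inside = e.quadratic_form(pts) <= 1.0
    if not inside.any():
        raise EmptyROIError("no voxel centre inside the ellipsoid")
    out[ii.ravel()[inside], jj.ravel()[inside], kk.ravel()[inside]] = True
    return Mask(out)
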