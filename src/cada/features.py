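"""Uptake and shape features: MEU, DI, SMU and the classical SBR.

Per striatum:

* MEU (mean ellipsoid uptake): mean normalized intensity inside the ROI of
  the fitted ellipsoid; reads like an SBR because the intensity
  normalization already plays the reference-region role.
* DI (dysmorphic index): ``1 − Π |E_i^S · E_i^T|`` over the three
  rank-paired unit eigenvectors of the subject and template ellipsoids;
  0 for a normally oriented striatum, 1 for maximal dysmorphism.
* SMU (shape-modulated uptake): ``MEU · (1 − DI)``.
* SBR: ``(C_str − C_occ) / C_occ`` from striatal and occipital reference
  ROI mean counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cada.ellipsoid import Ellipsoid, ellipsoid_roi, fit_ellipsoid, mask_surface_points
from cada.errors import DomainError, EmptyROIError
from cada.segmentation import SegmentationResult
from cada.volume_io import Mask, Volume, lr_axis

__all__ = [
    "FeatureRecord",
    "compute_meu",
    "compute_di",
    "compute_smu",
    "compute_sbr",
    "extract_features",
    "default_occipital_roi",
    "records_to_rows",
]

CSV_HEADER = ["subject_id", "meu_l", "meu_r", "di_l", "di_r",
              "smu_l", "smu_r", "sbr_l", "sbr_r", "flags"]


@dataclass
class FeatureRecord:
    """Per-subject uptake/shape features, one value per side."""

    subject_id: str
    meu_left: float = float("nan")
    meu_right: float = float("nan")
    di_left: float = float("nan")
    di_right: float = float("nan")
    smu_left: float = float("nan")
    smu_right: float = float("nan")
    sbr_left: float = float("nan")
    sbr_right: float = float("nan")
    flags: list[str] = field(default_factory=list)


def compute_meu(v: Volume, roi: Mask) -> float:
    """Arithmetic mean of the volume over the ROI voxels."""
    if roi.is_empty():
        raise EmptyROIError("MEU over an empty ROI")
    return float(v.data[roi.data].mean())


def compute_di(subject: Ellipsoid, template: Ellipsoid,
               *, degeneracy_rtol: float = 0.02) -> float:
    """Dysmorphic index between rank-paired ellipsoid eigenvector terns.

    Emits a warning when adjacent semi-axes of either ellipsoid are within
    ``degeneracy_rtol`` of each other, since rank pairing is then unstable.
    """
    for e in (subject, template):
        ratios = e.semi_axes[1:] / e.semi_axes[:-1]
        if np.any(ratios > 1 - degeneracy_rtol):
            warnings.warn(
                "near-degenerate ellipsoid axes; eigenvector pairing may be "
                "unstable", RuntimeWarning, stacklevel=2,
            )
            break
    s = subject.orientation / np.linalg.norm(subject.orientation, axis=1,
                                             keepdims=True)
    t = template.orientation / np.linalg.norm(template.orientation, axis=1,
                                              keepdims=True)
    dots = np.abs(np.einsum("ij,ij->i", s, t))
    return float(np.clip(1.0 - np.prod(dots), 0.0, 1.0))


def compute_smu(meu: float, di: float) -> float:
    """Shape-modulated uptake MEU · (1 − DI)."""
    if not (0.0 <= di <= 1.0):
        raise DomainError(f"DI must lie in [0, 1], got {di}")
    return meu * (1.0 - di)


def compute_sbr(v: Volume, striatal_roi: Mask, occipital_roi: Mask) -> float:
    """Specific binding ratio (C_str − C_occ)/C_occ from ROI mean counts."""
    if striatal_roi.is_empty() or occipital_roi.is_empty():
        raise EmptyROIError("SBR needs non-empty striatal and occipital ROIs")
    c_str = float(v.data[striatal_roi.data].mean())
    c_occ = float(v.data[occipital_roi.data].mean())
    if c_occ <= 0:
        raise DomainError(f"occipital reference mean must be > 0, got {c_occ}")
    return (c_str - c_occ) / c_occ


def default_occipital_roi(template: Volume, side: str = "none") -> Mask:
    """A fixed occipital reference box in template space.

    A posterior, mid-axial box spanning the central half of the left-right
    extent — a deterministic stand-in for the manually placed reference
    region of semi-quantitative protocols.  Users may supply their own mask.
    """
    shape = np.asarray(template.shape)
    axis = lr_axis(template.affine)
    # anterior-posterior axis: the non-LR axis with the larger extent
    others = [a for a in range(3) if a != axis]
    ap = max(others, key=lambda a: shape[a])
    z = [a for a in others if a != ap][0]
    sl = [slice(None)] * 3
    sl[axis] = slice(int(shape[axis] * 0.3), int(shape[axis] * 0.7))
    sl[ap] = slice(int(shape[ap] * 0.08), int(shape[ap] * 0.22))
    sl[z] = slice(int(shape[z] * 0.4), int(shape[z] * 0.6))
    data = np.zeros(template.shape, dtype=bool)
    data[tuple(sl)] = True
    return Mask(data, side=side)


def fit_side_ellipsoid(mask: Mask) -> Ellipsoid:
    """Fit the shape ellipsoid of one striatal mask from its surface voxels."""
    pts = mask_surface_points(mask)
    ell, _ = fit_ellipsoid(pts)
    return ell


def extract_features(v: Volume, seg: SegmentationResult,
                     template_ellipsoids: dict[str, Ellipsoid],
                     *, occipital_roi: Mask | None = None) -> FeatureRecord:
    """Compute the per-side feature record of one subject.

    Per side: fit the striatal ellipsoid, average uptake inside its ROI
    (MEU), compare its orientation with the matching-side template ellipsoid
    (DI), and combine (SMU).  A side whose fit or ROI fails is flagged and
    left as NaN rather than aborting the subject.
    """
    rec = FeatureRecord(subject_id=v.id)
    for side in ("left", "right"):
        mask: Mask = getattr(seg, side)
        try:
            ell = fit_side_ellipsoid(mask)
            roi = ellipsoid_roi(ell, v)
            meu = compute_meu(v, roi)
            di = compute_di(ell, template_ellipsoids[side])
            smu = compute_smu(meu, di)
        except Exception as exc:
            rec.flags.append(f"{side}:{type(exc).__name__}")
            continue
        setattr(rec, f"meu_{side}", meu)
        setattr(rec, f"di_{side}", di)
        setattr(rec, f"smu_{side}", smu)
        if occipital_roi is not None:
            try:
                setattr(rec, f"sbr_{side}", compute_sbr(v, mask, occipital_roi))
            except Exception as exc:
                rec.flags.append(f"{side}:sbr:{type(exc).__name__}")
    return rec


def records_to_rows(records: list[FeatureRecord]) -> list[dict]:
    """Flatten records into CSV-ready rows (see ``CSV_HEADER``)."""
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "meu_l": r.meu_left, "meu_r": r.meu_right,
            "di_l": r.di_left, "di_r": r.di_right,
            "smu_l": r.smu_left, "smu_r": r.smu_right,
            "sbr_l": r.sbr_left, "sbr_r": r.sbr_right,
            "flags": ";".join(r.flags),
        })
    return rows
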