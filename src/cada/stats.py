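"""Correlation of imaging features with motor severity.

SMU is related to clinical scores via Spearman rank correlation and two
regression models: ordinary least squares (y = b0 + b1·x) and an
exponential decay (y = a·exp(b·x)) fitted by nonlinear least squares on the
original scale, initialized from the log-linear OLS solution.  Adjusted R²
uses df = n − 2 for both models (one slope-like parameter beyond the
intercept equivalent), and no multiple-testing correction is applied across
the clinical-score family (flagged in the output metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from cada.errors import DegenerateInputError, DomainError, JoinError, SampleSizeError
from cada.features import FeatureRecord

__all__ = [
    "ClinicalRecord",
    "RegressionFit",
    "spearman",
    "fit_linear",
    "fit_exponential",
    "correlate_severity",
]


@dataclass
class ClinicalRecord:
    """Per-subject clinical row; PD-only fields are None for controls."""

    subject_id: str
    group: str                      # "PD" or "HC"
    updrs_me: float | None = None
    updrs_me_left: float | None = None
    updrs_me_right: float | None = None
    most_affected_side: str | None = None
    hy: float | None = None
    duration_years: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("PD", "HC"):
            raise ValueError(f"group must be PD or HC, got {self.group!r}")

    @property
    def updrs_me_mas(self) -> float | None:
        """Most-affected-side motor subscore."""
        if self.most_affected_side == "left":
            return self.updrs_me_left
        if self.most_affected_side == "right":
            return self.updrs_me_right
        return None


@dataclass
class RegressionFit:
    model: str                       # "linear" or "exponential"
    coefficients: dict[str, float]
    r2_adjusted: float
    p_value: float
    spearman_rho: float = float("nan")
    spearman_p: float = float("nan")
    n: int = 0
    converged: bool = True
    stderr: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "coefficients": self.coefficients,
            "stderr": self.stderr,
            "r2_adjusted": self.r2_adjusted,
            "p_value": self.p_value,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "n": self.n,
            "converged": self.converged,
            "metadata": self.metadata,
        }


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value comes from the standard t approximation.  Constant inputs
    leave the correlation undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or x.size != y.size:
        raise SampleSizeError("spearman needs paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _adj_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    n = y.size
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_linear(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """OLS fit y = b0 + b1·x with adjusted R² and slope significance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise SampleSizeError("linear fit needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("x is constant; design matrix is rank deficient")
    res = sps.linregress(x, y)
    yhat = res.intercept + res.slope * x
    return RegressionFit(
        model="linear",
        coefficients={"intercept": float(res.intercept), "slope": float(res.slope)},
        stderr={"slope": float(res.stderr), "intercept": float(res.intercept_stderr)},
        r2_adjusted=_adj_r2(y, yhat),
        p_value=float(res.pvalue),
        n=int(x.size),
        metadata={"df": int(x.size - 2)},
    )


def fit_exponential(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Nonlinear least squares y = a·exp(b·x) on the original scale.

    Initialized from the log-linear OLS solution, which requires y > 0.
    Adjusted R² is computed on the original y scale with df = n − 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise SampleSizeError("exponential fit needs n >= 3")
    if np.any(y <= 0):
        raise DomainError("exponential fit requires strictly positive y")
    b0 = sps.linregress(x, np.log(y))
    p_init = (float(np.exp(b0.intercept)), float(b0.slope))
    converged = True
    try:
        popt, pcov = optimize.curve_fit(
            lambda t, a, b: a * np.exp(b * t), x, y, p0=p_init, maxfev=10000,
        )
        perr = np.sqrt(np.diag(pcov))
    except RuntimeError:
        popt, perr, converged = np.asarray(p_init), np.full(2, np.nan), False
    a, b = float(popt[0]), float(popt[1])
    yhat = a * np.exp(b * x)
    # significance of the exponential rate via its Wald t statistic
    if np.isfinite(perr[1]) and perr[1] > 0:
        tstat = b / perr[1]
        pval = float(2 * sps.t.sf(abs(tstat), df=x.size - 2))
    else:
        pval = float("nan")
    return RegressionFit(
        model="exponential",
        coefficients={"a": a, "b": b},
        stderr={"a": float(perr[0]), "b": float(perr[1])},
        r2_adjusted=_adj_r2(y, yhat),
        p_value=pval,
        n=int(x.size),
        converged=converged,
        metadata={"df": int(x.size - 2), "criterion": "least squares on original scale"},
    )


def correlate_severity(
    features: list[FeatureRecord],
    clinical: list[ClinicalRecord],
    mode: str = "mean_smu",
) -> dict[str, RegressionFit]:
    """Correlate SMU with UPDRS motor scores over the PD group.

    ``mode="mean_smu"``: x = (SMU_left + SMU_right)/2 against the total
    UPDRS-ME score.  ``mode="mas"``: x = SMU contralateral to the most
    affected side against the UPDRS-ME-MAS subscore.  Returns Spearman
    statistics attached to both a linear and an exponential fit.
    """
    if mode not in ("mean_smu", "mas"):
        raise ValueError(f"mode must be mean_smu or mas, got {mode!r}")
    feats = {f.subject_id: f for f in features}
    xs, ys = [], []
    for c in clinical:
        if c.group != "PD" or c.subject_id not in feats:
            continue
        f = feats[c.subject_id]
        if mode == "mean_smu":
            if c.updrs_me is None:
                continue
            x = 0.5 * (f.smu_left + f.smu_right)
            y = c.updrs_me
        else:
            y = c.updrs_me_mas
            if y is None or c.most_affected_side is None:
                continue
            # striatal damage is contralateral to the clinical side
            x = f.smu_right if c.most_affected_side == "left" else f.smu_left
        if np.isfinite(x) and np.isfinite(y):
            xs.append(x)
            ys.append(y)
    if not xs:
        raise JoinError("no PD subjects with both features and clinical scores")
    x = np.asarray(xs)
    y = np.asarray(ys)
    rho, p = spearman(x, y)
    lin = fit_linear(x, y)
    expo = fit_exponential(x, y)
    for fit in (lin, expo):
        fit.spearman_rho, fit.spearman_p = rho, p
        fit.metadata["mode"] = mode
        fit.metadata["multiple_testing_correction"] = "none"
    return {"linear": lin, "exponential": expo}
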