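"""SVM classification of parkinsonian vs control subjects.

Four feature configurations mirror the evaluation experiments:
MEU only (exp1_meu), DI only (exp2_di), all four measures (exp3_all),
SMU only (exp4_smu), plus an SBR configuration for the semi-quantitative
arm.  Features are standardized on the training fold; the default
evaluation is leave-one-out cross-validation with a linear-kernel SVM
(resubstitution is available, clearly labeled, for legacy-style tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from cada.errors import ClassBalanceError
from cada.features import FeatureRecord

__all__ = ["ExperimentConfig", "ClassificationReport", "build_design", "evaluate"]

EXPERIMENT_COLUMNS: dict[str, list[str]] = {
    "exp1_meu": ["meu_left", "meu_right"],
    "exp2_di": ["di_left", "di_right"],
    "exp3_all": ["meu_left", "meu_right", "di_left", "di_right"],
    "exp4_smu": ["smu_left", "smu_right"],
    "sbr": ["sbr_left", "sbr_right"],
}

POSITIVE_LABEL = "PD"


@dataclass
class ExperimentConfig:
    name: str = "exp4_smu"
    kernel: str = "linear"
    cv: str = "loo"          # "loo" or "none" (resubstitution)
    seed: int = 17
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_COLUMNS:
            raise ValueError(
                f"unknown experiment {self.name!r}; choose from "
                f"{sorted(EXPERIMENT_COLUMNS)}"
            )
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be linear or rbf, got {self.kernel!r}")
        if self.cv not in ("loo", "none"):
            raise ValueError(f"cv must be loo or none, got {self.cv!r}")


@dataclass
class ClassificationReport:
    """Rates in percent; AUC in [0, 1] (multiply by 100 for table style)."""

    correct_rate: float
    auc: float
    sensitivity: float
    specificity: float
    n_pd: int
    n_hc: int
    cv: str
    per_subject: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "correct_rate": self.correct_rate,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_pd": self.n_pd,
            "n_hc": self.n_hc,
            "cv": self.cv,
            "per_subject": self.per_subject,
        }

    def summary(self) -> str:
        return (
            f"SVM report ({self.cv}, {self.n_pd} PD / {self.n_hc} HC)\n"
            f"  correct rate : {self.correct_rate:6.2f} %\n"
            f"  AUC          : {self.auc:6.4f}\n"
            f"  sensitivity  : {self.sensitivity:6.2f} %\n"
            f"  specificity  : {self.specificity:6.2f} %"
        )


def build_design(
    records: list[FeatureRecord],
    config: ExperimentConfig,
    groups: dict[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray | None, list[str], list[str]]:
    """Assemble the design matrix for an experiment configuration.

    Subjects with a missing (NaN or flagged) value in any selected column are
    excluded and their ids returned.  ``groups`` maps subject id to
    "PD"/"HC"; labels are None when it is not given.
    """
    cols = EXPERIMENT_COLUMNS[config.name]
    rows, ids, excluded = [], [], []
    for r in records:
        vals = [getattr(r, c) for c in cols]
        if any(not np.isfinite(v) for v in vals) or (
                groups is not None and r.subject_id not in groups):
            excluded.append(r.subject_id)
            continue
        rows.append(vals)
        ids.append(r.subject_id)
    X = np.asarray(rows, dtype=float).reshape(len(rows), len(cols))
    y = None
    if groups is not None:
        y = np.asarray([groups[i] for i in ids])
    return X, y, ids, excluded


def _fit_clf(config: ExperimentConfig):
    return make_pipeline(
        StandardScaler(),
        SVC(kernel=config.kernel, C=config.C, random_state=config.seed),
    )


def evaluate(X: np.ndarray, y: np.ndarray, config: ExperimentConfig,
             ids: list[str] | None = None) -> ClassificationReport:
    """Evaluate an SVM on the design matrix.

    ``cv="loo"`` gives leave-one-out cross-validated predictions and decision
    values; ``cv="none"`` is resubstitution.  Sensitivity counts correctly
    flagged PD subjects, specificity correctly flagged controls, and the AUC
    uses signed decision values with PD positive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ClassBalanceError(f"need two classes, got {classes.tolist()}")
    n = len(y)
    preds = np.empty(n, dtype=object)
    scores = np.empty(n, dtype=float)
    if config.cv == "loo":
        for i in range(n):
            train = np.ones(n, dtype=bool)
            train[i] = False
            if np.unique(y[train]).size < 2:
                raise ClassBalanceError(
                    "leave-one-out fold lost a class; need >= 2 per class"
                )
            clf = _fit_clf(config).fit(X[train], y[train])
            preds[i] = clf.predict(X[i:i + 1])[0]
            scores[i] = _pd_score(clf, X[i:i + 1])
    else:
        clf = _fit_clf(config).fit(X, y)
        preds[:] = clf.predict(X)
        scores[:] = np.array([_pd_score(clf, X[i:i + 1]) for i in range(n)])

    is_pd = y == POSITIVE_LABEL
    correct = preds == y
    sens = 100.0 * correct[is_pd].mean() if is_pd.any() else float("nan")
    spec = 100.0 * correct[~is_pd].mean() if (~is_pd).any() else float("nan")
    auc = float(roc_auc_score(is_pd.astype(int), scores))
    per_subject = [
        {"id": (ids[i] if ids else str(i)), "label": str(y[i]),
         "pred": str(preds[i]), "decision": float(scores[i])}
        for i in range(n)
    ]
    return ClassificationReport(
        correct_rate=100.0 * correct.mean(), auc=auc,
        sensitivity=float(sens), specificity=float(spec),
        n_pd=int(is_pd.sum()), n_hc=int((~is_pd).sum()),
        cv=config.cv, per_subject=per_subject,
    )


def _pd_score(clf, x: np.ndarray) -> float:
    """Signed decision value oriented so larger means more PD-like."""
    val = float(clf.decision_function(x)[0])
    # SVC orients decision_function toward classes_[1]
    if clf.classes_[1] != POSITIVE_LABEL:
        val = -val
    return val
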