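"""RBF-SVM fatigue/normal classification under stratified k-fold CV.

The default protocol mirrors per-subject reporting: each subject's epochs
are split into 10 stratified folds, a support-vector machine with a
radial-basis-function kernel is trained on 9 folds and tested on the 10th,
and the per-subject mean accuracy plus a cohort mean +/- SD summary are
assembled.  Feature standardisation is fit on each training fold only, so
no information leaks from test folds into the scalers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import feature_columns

logger = logging.getLogger(__name__)

__all__ = ["CVConfig", "CVReport", "kfold_cross_validate", "fit_predict", "summarize"]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and SVM settings.

    ``kernel_width_rule`` is either the name of a heuristic ("scale":
    gamma = 1 / (n_features * Var(X_train)); "auto": 1 / n_features) or an
    explicit positive float.  ``per_subject=True`` runs an independent CV
    within each subject (per-subject accuracies as in a per-subject report
    table); ``False`` pools all subjects into subject-blind folds.
    """

    n_folds: int = 10
    stratified: bool = True
    rng_seed: int = 0
    svm_C: float = 1.0
    kernel_width_rule: str | float = "scale"
    per_subject: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.svm_C <= 0:
            raise ValueError(f"svm_C must be positive, got {self.svm_C}")
        if isinstance(self.kernel_width_rule, str):
            if self.kernel_width_rule not in ("scale", "auto"):
                raise ValueError(
                    "kernel_width_rule must be 'scale', 'auto' or a positive float"
                )
        elif not self.kernel_width_rule > 0:
            raise ValueError("explicit kernel width must be positive")


@dataclass
class CVReport:
    """Cross-validation results in a per-subject report shape.

    ``per_subject`` maps subject id to fold accuracies and their mean;
    ``cohort_mean`` is the mean of per-subject means and
    ``cohort_dispersion`` their dispersion, labelled by
    ``dispersion_label`` (``"sd"``).
    """

    per_subject: dict
    cohort_mean: float
    cohort_dispersion: float
    dispersion_label: str
    config: dict
    skipped: dict = field(default_factory=dict)

    @property
    def n_test_samples(self) -> int:
        return sum(s["n_samples"] for s in self.per_subject.values())

    def to_dict(self) -> dict:
        return {
            "per_subject": self.per_subject,
            "cohort_mean": self.cohort_mean,
            "cohort_dispersion": self.cohort_dispersion,
            "dispersion_label": self.dispersion_label,
            "config": self.config,
            "skipped": self.skipped,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def _make_svm(cfg: CVConfig) -> Pipeline:
    gamma = cfg.kernel_width_rule
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(C=cfg.svm_C, kernel="rbf", gamma=gamma)),
        ]
    )


def _cv_accuracies(X: np.ndarray, y: np.ndarray, cfg: CVConfig) -> list[float]:
    if cfg.stratified:
        splitter = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.rng_seed
        )
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.rng_seed)
    accs = []
    for train_idx, test_idx in splitter.split(X, y):
        model = _make_svm(cfg)
        model.fit(X[train_idx], y[train_idx])
        accs.append(float(model.score(X[test_idx], y[test_idx])))
    return accs


def kfold_cross_validate(table: pd.DataFrame, cfg: CVConfig = CVConfig()) -> CVReport:
    """Stratified k-fold cross-validation of the RBF-SVM on a feature table.

    Deterministic given ``cfg.rng_seed``.  In per-subject mode a subject
    missing one of the two classes, or with fewer samples of a class than
    folds, is skipped with a logged reason; pooling mode treats the whole
    table as one sample set under a single pseudo-subject key ``"pooled"``.
    """
    feats = feature_columns(table)
    if not feats:
        raise ValueError("feature table has no fuzzyen_<channel> columns")
    if not np.all(np.isfinite(table[feats].to_numpy())):
        raise ValueError("non-finite feature values")

    groups = (
        table.groupby("subject_id", sort=True)
        if cfg.per_subject
        else [("pooled", table)]
    )
    per_subject: dict = {}
    skipped: dict = {}
    for subject, sub in groups:
        y = sub["label"].to_numpy(dtype=int)
        counts = np.bincount(y, minlength=2)
        if counts.min() == 0:
            skipped[str(subject)] = "one class absent"
            logger.warning("subject %s skipped: one class absent", subject)
            continue
        if counts.min() < cfg.n_folds:
            raise ValueError(
                f"subject {subject}: smallest class has {counts.min()} samples, "
                f"fewer than n_folds={cfg.n_folds}; use a smaller n_folds"
            )
        X = sub[feats].to_numpy(dtype=float)
        accs = _cv_accuracies(X, y, cfg)
        per_subject[str(subject)] = {
            "fold_accuracies": accs,
            "mean_accuracy": float(np.mean(accs)),
            "n_samples": int(len(y)),
        }
    if not per_subject:
        raise ValueError("no subject had both classes; nothing to cross-validate")
    means = np.array([s["mean_accuracy"] for s in per_subject.values()])
    cfg_echo = asdict(cfg)
    return CVReport(
        per_subject=per_subject,
        cohort_mean=float(means.mean()),
        cohort_dispersion=float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        dispersion_label="sd",
        config=cfg_echo,
        skipped=skipped,
    )


def fit_predict(
    train: pd.DataFrame, test: pd.DataFrame, cfg: CVConfig = CVConfig()
) -> tuple[np.ndarray, float]:
    """Fit the RBF-SVM on ``train`` and predict ``test``.

    Returns the predicted labels and the test accuracy.
    """
    feats = feature_columns(train)
    y_train = train["label"].to_numpy(dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    if len(test) == 0:
        raise ValueError("empty test set")
    model = _make_svm(cfg)
    model.fit(train[feats].to_numpy(dtype=float), y_train)
    X_test = test[feats].to_numpy(dtype=float)
    pred = model.predict(X_test)
    acc = float(np.mean(pred == test["label"].to_numpy(dtype=int)))
    return pred, acc


def summarize(report: CVReport) -> str:
    """Render a plain-text accuracy table: one row per subject plus a
    ``MEAN +/- SD`` summary row."""
    lines = [f"{'No. of subject':<16}{'Accuracy':>10}"]
    for subject, stats in report.per_subject.items():
        lines.append(f"{subject:<16}{stats['mean_accuracy']:>10.2f}")
    lines.append(
        f"{'MEAN +/- SD':<16}{report.cohort_mean:>10.2f} +/- {report.cohort_dispersion:.3f}"
    )
    return "\n".join(lines)
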