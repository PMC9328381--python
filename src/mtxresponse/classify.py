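"""Nested cross-validated classification of methotrexate nonresponse.

Three model families — L2-regularized logistic regression, random forest, and
a pathway-supported variant (pathway-mean aggregation of standardized gene
features feeding the L2 family) — are evaluated under a stratified 10-fold
outer / 5-fold inner nested cross-validation.  Inner folds select
hyperparameters by ROC AUC; standardization is refit inside every outer
training fold so no information flows from held-out patients into training.

The positive class throughout is "nonresponder" (the clinical target is early
detection of patients who will not benefit from methotrexate).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .data import ConfigError, PipelineError
from .features import FeatureMatrix, apply_standardizer, fit_standardizer

logger = logging.getLogger(__name__)

FAMILIES = ("l2_logistic", "random_forest", "pathway_supported")
POSITIVE_LABEL = "nonresponder"

#: 7 log-spaced L2 penalty strengths (sklearn C = inverse regularization)
_L2_GRID = [{"C": float(c)} for c in np.logspace(-3, 3, 7)]
_RF_GRID = [
    {"n_estimators": n, "max_depth": d}
    for n in (200, 500)
    for d in (None, 8)
]


@dataclass
class ModelSpec:
    """Model family plus its hyperparameter grid.

    ``pathway_supported`` additionally needs a ``pathways`` map (term id ->
    member gene set); member genes are averaged after standardization and the
    resulting pathway features are fed to the L2-logistic grid.
    """

    family: str
    hyperparameter_grid: list[dict[str, Any]] | None = None
    inner_selection_metric: str = "roc_auc"
    pathways: dict[str, set[str]] | None = None
    min_pathway_genes: int = 1

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        if self.inner_selection_metric != "roc_auc":
            raise ConfigError("only roc_auc inner selection is implemented")
        if self.hyperparameter_grid is None:
            self.hyperparameter_grid = list(_RF_GRID if self.family == "random_forest" else _L2_GRID)
        if not self.hyperparameter_grid:
            raise ConfigError("hyperparameter grid must be non-empty")
        if self.family == "pathway_supported" and not self.pathways:
            raise ConfigError("pathway_supported family requires a pathways map")


@dataclass
class CVResult:
    """Nested-CV output: per-fold metrics, pooled held-out scores, summaries."""

    fold_metrics: pd.DataFrame          # fold, roc_auc, balanced_accuracy, chosen params
    scores: pd.Series                   # pooled held-out score per patient (scored exactly once)
    labels: pd.Series                   # true response per patient
    summary: dict[str, float]           # mean/sem of each metric
    coefficient_summary: pd.DataFrame | None  # per-feature mean +/- SD (linear families)
    fold_artifacts: list[dict]          # per fold: standardizer params + chosen hyperparameters
    family: str
    seed: int
    k_outer: int
    k_inner: int

    def training_checksums(self) -> list[str]:
        """Per-fold digest of everything estimated on training data
        (standardizer parameters and chosen hyperparameters); used by leakage
        tests to assert independence from held-out values."""
        out = []
        for art in self.fold_artifacts:
            h = hashlib.sha256()
            h.update(np.asarray(art["standardizer_mean"], dtype=float).tobytes())
            h.update(np.asarray(art["standardizer_sd"], dtype=float).tobytes())
            h.update(repr(sorted(art["chosen_params"].items())).encode())
            out.append(h.hexdigest())
        return out


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class recalls; requires both classes in the truth."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise PipelineError("balanced accuracy undefined: only one class present in truth")
    return float(balanced_accuracy_score(y_true, np.asarray(y_pred)))


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC (Mann-Whitney with half-credit for ties)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise PipelineError("ROC AUC undefined: only one class present in truth")
    if np.allclose(scores, scores[0]):
        warnings.warn("constant scores: ROC AUC defaults to 0.5", stacklevel=2)
        return 0.5
    return float(roc_auc_score(y_true, scores))


def threshold_prediction(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary prediction: positive iff score >= threshold."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def nonresponder_detection_curve(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Trade-off curve: fraction of true nonresponders detected vs fraction of
    good responders misclassified as nonresponders, swept over thresholds.

    This is the ROC curve with nonresponder as the positive class; it steps
    monotonically from (0, 0) to (1, 1).
    """
    y = _binarize(pd.Series(np.asarray(labels)))
    fpr, tpr, thresholds = roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({
        "good_misclassified_fraction": fpr,
        "nonresponders_detected_fraction": tpr,
        "threshold": thresholds,
    })


def detection_at_misclassification(curve: pd.DataFrame, max_misclassified: float) -> float:
    """Highest nonresponder detection achievable while misclassifying at most
    the given fraction of good responders."""
    ok = curve["good_misclassified_fraction"] <= max_misclassified + 1e-12
    return float(curve.loc[ok, "nonresponders_detected_fraction"].max())


def pathway_aggregate(
    features: FeatureMatrix,
    pathways: dict[str, set[str]],
    min_genes: int = 1,
) -> FeatureMatrix:
    """Collapse gene-level features to pathway-level means.

    One feature per pathway with at least ``min_genes`` members present in the
    input; genes in no retained pathway are dropped.  Inputs are expected to be
    standardized so the unweighted mean is a scale-free module score.
    """
    rows = {}
    index = pd.Index(features.feature_ids)
    for term in sorted(pathways):
        members = index.intersection(sorted(pathways[term]))
        if len(members) >= min_genes and len(members) > 0:
            rows[term] = features.frame.loc[members].mean(axis=0)
    if not rows:
        raise PipelineError("no pathway retains enough member genes after restriction")
    frame = pd.DataFrame(rows).T
    return FeatureMatrix(frame, features.contrast_tag)


def summarize_importance(per_fold_coefficients: list[pd.Series] | pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean +/- SD (sample SD) of model coefficients across folds,
    ordered by decreasing |mean|."""
    if isinstance(per_fold_coefficients, list):
        coef = pd.DataFrame(per_fold_coefficients)
    else:
        coef = per_fold_coefficients
    out = pd.DataFrame({"mean": coef.mean(axis=0), "sd": coef.std(axis=0, ddof=1)})
    return out.reindex(out["mean"].abs().sort_values(ascending=False).index)


def _binarize(labels: pd.Series) -> np.ndarray:
    vals = set(labels.unique())
    if not vals <= {"good", POSITIVE_LABEL}:
        raise ConfigError(f"labels must be good/{POSITIVE_LABEL}, got {sorted(vals)}")
    return (labels == POSITIVE_LABEL).to_numpy().astype(int)


def _make_estimator(family: str, params: dict[str, Any], seed: int):
    if family in ("l2_logistic", "pathway_supported"):
        # liblinear default penalty is the L2 ridge this family is named for
        return LogisticRegression(solver="liblinear", max_iter=2000, **params)
    return RandomForestClassifier(
        max_features="sqrt", random_state=seed, n_jobs=1, **params)


def nested_cv(
    features: FeatureMatrix,
    labels: pd.Series,
    spec: ModelSpec,
    k_outer: int = 10,
    k_inner: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified nested cross-validation of one model family.

    Outer folds estimate held-out performance; within each outer training fold
    the standardizer is refit, pathway aggregation (if any) is applied with
    those training parameters, and hyperparameters are chosen by mean ROC AUC
    over an inner stratified ``k_inner``-fold loop (ties resolved toward the
    first grid entry).  Every patient is scored exactly once across outer test
    folds.  Fully deterministic given the seed.
    """
    labels = labels.loc[features.patient_ids]
    y_all = _binarize(labels)
    class_counts = np.bincount(y_all, minlength=2)
    if class_counts.min() < k_outer:
        raise PipelineError(
            f"stratification error: smallest class has {class_counts.min()} patients < k_outer={k_outer}"
        )
    patients = np.array(features.patient_ids)
    rng_seed = int(seed) % (2**31)
    outer = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=rng_seed)

    fold_rows = []
    artifacts = []
    coef_rows: list[pd.Series] = []
    pooled_scores = pd.Series(np.nan, index=features.patient_ids, dtype=float)

    for fold_idx, (tr, te) in enumerate(outer.split(patients, y_all)):
        train_p, test_p = patients[tr].tolist(), patients[te].tolist()
        std = fit_standardizer(features, train_p)
        z_all = apply_standardizer(std, features)
        if spec.family == "pathway_supported":
            z_all = pathway_aggregate(z_all, spec.pathways, spec.min_pathway_genes)
        x_train = z_all.frame[train_p].to_numpy().T
        x_test = z_all.frame[test_p].to_numpy().T
        y_train, y_test = y_all[tr], y_all[te]

        inner = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=rng_seed + 1 + fold_idx)
        inner_splits = list(inner.split(x_train, y_train))
        best_params, best_auc = None, -np.inf
        for params in spec.hyperparameter_grid:
            aucs = []
            for in_tr, in_val in inner_splits:
                est = _make_estimator(spec.family, params, rng_seed + 7919 * (fold_idx + 1))
                est.fit(x_train[in_tr], y_train[in_tr])
                val_scores = est.predict_proba(x_train[in_val])[:, 1]
                aucs.append(roc_auc(y_train[in_val], val_scores))
            mean_auc = float(np.mean(aucs))
            if mean_auc > best_auc + 1e-12:
                best_auc, best_params = mean_auc, params

        est = _make_estimator(spec.family, best_params, rng_seed + 7919 * (fold_idx + 1))
        est.fit(x_train, y_train)
        test_scores = est.predict_proba(x_test)[:, 1]
        pooled_scores.loc[test_p] = test_scores

        fold_rows.append({
            "fold": fold_idx,
            "roc_auc": roc_auc(y_test, test_scores),
            "balanced_accuracy": balanced_accuracy(y_test, threshold_prediction(test_scores, 0.5)),
            "chosen_params": dict(best_params),
            "inner_auc": best_auc,
        })
        artifacts.append({
            "standardizer_mean": std.mean.to_numpy(),
            "standardizer_sd": std.sd.to_numpy(),
            "chosen_params": dict(best_params),
            "test_patients": list(test_p),
        })
        if hasattr(est, "coef_"):
            coef_rows.append(pd.Series(est.coef_.ravel(), index=z_all.feature_ids, name=fold_idx))

    fold_metrics = pd.DataFrame(fold_rows)
    summary = {}
    for metric in ("roc_auc", "balanced_accuracy"):
        vals = fold_metrics[metric].to_numpy()
        summary[f"{metric}_mean"] = float(vals.mean())
        summary[f"{metric}_sem"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))

    coef_summary = summarize_importance(coef_rows) if coef_rows else None
    return CVResult(
        fold_metrics=fold_metrics,
        scores=pooled_scores,
        labels=labels,
        summary=summary,
        coefficient_summary=coef_summary,
        fold_artifacts=artifacts,
        family=spec.family,
        seed=seed,
        k_outer=k_outer,
        k_inner=k_inner,
    )
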