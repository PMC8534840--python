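"""ROC/AUC evaluation, cross-validated and cross-species protocols.

ROC curves are generated by sweeping the decision threshold over every
distinct observed score (plus sentinels at ±infinity): at threshold ``t``
a sequence is declared coding iff its score is strictly greater than
``t``, so tied scores move together and the curve interpolates ties
linearly (half credit per tied coding/noncoding pair).  The trapezoidal
area under this curve equals the Mann-Whitney probability
``P(score_coding > score_noncoding) + 0.5 * P(tie)``.

Sensitivity and specificity are reported at the fixed threshold 0: coding
windows with positive score are true positives, noncoding windows with
score ≤ 0 are true negatives.

Cross-validation pools the test-fold scores of all folds into a single
score set and computes one ROC/AUC and one sensitivity/specificity from
the pooled scores, so every score participates in the threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import TrainedModel, score_many, train_centroid, train_svm
from .dataset import LabeledDataset, kfold_split
from .profiles import ProfileVector, profile_matrix

__all__ = [
    "EvaluationError",
    "EvaluationResult",
    "roc_curve",
    "auc",
    "sens_spec_at_zero",
    "evaluate_scores",
    "cross_validate",
    "cross_species",
    "cross_species_matrix",
    "centroid_profiles",
    "results_table",
    "write_roc_tsv",
]


class EvaluationError(ValueError):
    pass


@dataclass
class EvaluationResult:
    """Scores, ROC points and threshold-0 operating point for one condition."""

    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    metadata: dict = field(default_factory=dict)


def _check_labels(labels: np.ndarray) -> None:
    if not ((labels == 1).any() and (labels == 0).any()):
        raise EvaluationError("both classes must be present to evaluate")


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) from a strict ``score > threshold`` sweep.

    Thresholds are the distinct observed scores in descending order plus a
    ``-inf`` sentinel: under the strict ``>`` rule the maximum score is the
    threshold producing (0,0), and only the sentinel reaches (1,1), so the
    curve always spans (0,0)–(1,1) and is sorted by false-positive rate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    P = int(y.sum())
    N = y.size - P
    # indices where a tie group ends (cumulative counts *after* the group)
    group_end = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    tps = np.r_[0, np.cumsum(y)[group_end]]
    fps = np.r_[0, np.cumsum(1 - y)[group_end]]
    # threshold t yields positives = {score > t}: t = v_i gives the point
    # *before* tie group i is included; only t below the minimum score
    # (sentinel -inf) reaches (1,1)
    thresholds = np.r_[s[group_end], -np.inf]
    return fps / N, tps / P, thresholds


def auc(fpr, tpr) -> float:
    """Trapezoidal area under an ROC curve given as (fpr, tpr) points."""
    return float(np.trapezoid(np.asarray(tpr), np.asarray(fpr)))


def sens_spec_at_zero(scores, labels) -> tuple[float, float]:
    """Sensitivity and specificity at the fixed threshold 0 (strict >)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    tp = int(((s > 0) & (y == 1)).sum())
    fn = int(((s <= 0) & (y == 1)).sum())
    tn = int(((s <= 0) & (y == 0)).sum())
    fp = int(((s > 0) & (y == 0)).sum())
    return tp / (tp + fn), tn / (tn + fp)


def evaluate_scores(scores, labels, metadata: dict | None = None) -> EvaluationResult:
    """Bundle ROC, AUC and the threshold-0 operating point for a score set."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    fpr, tpr, _ = roc_curve(s, y)
    sens, spec = sens_spec_at_zero(s, y)
    tp = int(((s > 0) & (y == 1)).sum())
    fp = int(((s > 0) & (y == 0)).sum())
    tn = int(((s <= 0) & (y == 0)).sum())
    fn = int(((s <= 0) & (y == 1)).sum())
    return EvaluationResult(
        s, y, fpr, tpr, auc(fpr, tpr), sens, spec, tp, fp, tn, fn,
        dict(metadata or {}),
    )


# ---------------------------------------------------------------------------
# protocols


def _train(X, y, classifier: str, C: float, kind: str, K: int, species: str) -> TrainedModel:
    if classifier == "linear-svm":
        return train_svm(X, y, C=C, profile_kind=kind, max_lag=K, species_id=species)
    if classifier == "centroid":
        return train_centroid(X, y, profile_kind=kind, max_lag=K, species_id=species)
    raise EvaluationError(f"unknown classifier {classifier!r}")


def cross_validate(
    dataset: LabeledDataset,
    profile_kind: str = "eaAMI",
    max_lag: int = 6,
    classifier: str = "linear-svm",
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> EvaluationResult:
    """k-fold CV with pooled test-fold scores (one ROC per condition)."""
    X = profile_matrix(dataset.sequences, profile_kind, max_lag)
    y = dataset.labels
    scores = np.empty(y.size)
    for train_idx, test_idx in kfold_split(dataset, k=k, seed=seed):
        model = _train(
            X[train_idx], y[train_idx], classifier, C,
            profile_kind, max_lag, dataset.species_id,
        )
        scores[test_idx] = score_many(model, X[test_idx])
    return evaluate_scores(
        scores, y,
        metadata={
            "protocol": "cv",
            "profile_kind": profile_kind,
            "max_lag": max_lag,
            "classifier": classifier,
            "k": k,
            "seed": seed,
            "seq_length": dataset.seq_length,
            "train_species": dataset.species_id,
            "test_species": dataset.species_id,
            "n": int(y.size),
        },
    )


def cross_species(
    train_dataset: LabeledDataset,
    test_dataset: LabeledDataset,
    profile_kind: str = "eaAMI",
    max_lag: int = 6,
    classifier: str = "linear-svm",
    C: float = 1.0,
) -> EvaluationResult:
    """Train on all of one species' dataset, score all of another's."""
    X_train = profile_matrix(train_dataset.sequences, profile_kind, max_lag)
    model = _train(
        X_train, train_dataset.labels, classifier, C,
        profile_kind, max_lag, train_dataset.species_id,
    )
    X_test = profile_matrix(test_dataset.sequences, profile_kind, max_lag)
    scores = score_many(model, X_test)
    return evaluate_scores(
        scores, test_dataset.labels,
        metadata={
            "protocol": "cross-species",
            "profile_kind": profile_kind,
            "max_lag": max_lag,
            "classifier": classifier,
            "seq_length": test_dataset.seq_length,
            "train_species": train_dataset.species_id,
            "test_species": test_dataset.species_id,
            "n": int(test_dataset.labels.size),
        },
    )


def cross_species_matrix(
    datasets: Sequence[LabeledDataset],
    profile_kind: str = "eaAMI",
    max_lag: int = 6,
    classifier: str = "linear-svm",
    C: float = 1.0,
) -> list[EvaluationResult]:
    """All ordered train/test species pairs (S x S results, diagonal included)."""
    return [
        cross_species(tr, te, profile_kind, max_lag, classifier, C)
        for tr in datasets
        for te in datasets
    ]


def centroid_profiles(
    dataset: LabeledDataset, profile_kind: str = "AMI", max_lag: int = 16
) -> tuple[ProfileVector, ProfileVector]:
    """Per-class mean profiles (coding, noncoding), e.g. for plotting."""
    X = profile_matrix(dataset.sequences, profile_kind, max_lag)
    y = dataset.labels
    _check_labels(y)
    return (
        ProfileVector(profile_kind, max_lag, X[y == 1].mean(axis=0)),
        ProfileVector(profile_kind, max_lag, X[y == 0].mean(axis=0)),
    )


# ---------------------------------------------------------------------------
# tabular export


def results_table(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """One row per evaluated condition: metadata plus AUC/SN/SP and counts."""
    rows = []
    for r in results:
        row = dict(r.metadata)
        row.update(
            auc=r.auc, sensitivity=r.sensitivity, specificity=r.specificity,
            tp=r.tp, fp=r.fp, tn=r.tn, fn=r.fn,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_roc_tsv(path, result: EvaluationResult) -> None:
    pd.DataFrame({"fpr": result.fpr, "tpr": result.tpr}).to_csv(
        path, sep="\t", index=False
    )
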