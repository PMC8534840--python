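"""Linear-SVM and Euclidean-centroid classification of profile vectors.

Both classifiers emit a signed score with the convention **positive score
⇒ coding**.  For the SVM the score is the signed distance-proportional
decision value ``w · standardize(x) + b``; features are standardized with
training-set statistics because profile components differ in scale across
lags and margin-based training is scale-sensitive.  The centroid
classifier works on raw profiles: its score is ``dist(x, noncoding
centroid) − dist(x, coding centroid)``, positive when the profile lies
closer to the coding centroid.

Because the label-to-sign mapping of SVM solvers is an implementation
detail, orientation is calibrated after training: if the mean score of the
coding training examples is not positive, the weight vector and bias are
flipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .profiles import ProfileVector

__all__ = [
    "ModelError",
    "TrainedModel",
    "train_svm",
    "train_centroid",
    "score",
    "score_many",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class ModelError(ValueError):
    pass


@dataclass
class TrainedModel:
    """A trained linear-SVM or centroid classifier over one profile space."""

    classifier_kind: str  # "linear-svm" | "centroid"
    profile_kind: str  # "AMI" | "eAMI" | "eaAMI"
    max_lag: int
    species_id: str = ""
    # linear-svm fields
    weights: np.ndarray | None = None
    bias: float | None = None
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    # centroid fields
    centroid_coding: np.ndarray | None = None
    centroid_noncoding: np.ndarray | None = None

    @property
    def dim(self) -> int:
        if self.classifier_kind == "linear-svm":
            return self.weights.shape[0]
        return self.centroid_coding.shape[0]


def _stack(profiles, profile_kind=None, max_lag=None) -> tuple[np.ndarray, str | None, int | None]:
    """Accept either a 2-D array or a list of ProfileVector."""
    if isinstance(profiles, np.ndarray):
        return np.atleast_2d(profiles), profile_kind, max_lag
    if profiles and isinstance(profiles[0], ProfileVector):
        kinds = {p.kind for p in profiles}
        lags = {p.max_lag for p in profiles}
        if len(kinds) > 1 or len(lags) > 1:
            raise ModelError("profiles mix kinds or max_lag values")
        return (
            np.vstack([p.values for p in profiles]),
            kinds.pop(),
            lags.pop(),
        )
    return np.atleast_2d(np.asarray(profiles, dtype=float)), profile_kind, max_lag


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ModelError("training data contains a single class")


def train_svm(
    profiles,
    labels,
    C: float = 1.0,
    profile_kind: str = "eaAMI",
    max_lag: int = 6,
    species_id: str = "",
) -> TrainedModel:
    """Fit a linear soft-margin SVM on standardized profiles.

    The decision rule is collapsed to an explicit weight vector and bias so
    that scoring is a dot product and models serialize to plain JSON.
    """
    X, kind, K = _stack(profiles, profile_kind, max_lag)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise ModelError("profiles and labels disagree in length")
    _check_two_classes(y)

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0  # constant features carry no information; leave centered
    Xs = (X - mean) / std

    svm = SVC(kernel="linear", C=C)
    svm.fit(Xs, y)
    w = svm.coef_.ravel().copy()
    b = float(svm.intercept_[0])

    scores = Xs @ w + b
    if scores[y == 1].mean() <= 0:  # enforce positive ⇒ coding
        w, b = -w, -b
    return TrainedModel(
        "linear-svm", kind, K, species_id,
        weights=w, bias=b, scaler_mean=mean, scaler_scale=std,
    )


def train_centroid(
    profiles,
    labels,
    profile_kind: str = "eaAMI",
    max_lag: int = 6,
    species_id: str = "",
) -> TrainedModel:
    """Per-class arithmetic-mean centroids on raw (unstandardized) profiles."""
    X, kind, K = _stack(profiles, profile_kind, max_lag)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise ModelError("profiles and labels disagree in length")
    _check_two_classes(y)
    return TrainedModel(
        "centroid", kind, K, species_id,
        centroid_coding=X[y == 1].mean(axis=0),
        centroid_noncoding=X[y == 0].mean(axis=0),
    )


def _check_profile(model: TrainedModel, kind: str | None, K: int | None, dim: int) -> None:
    if kind is not None and kind != model.profile_kind:
        raise ModelError(
            f"profile kind {kind!r} does not match model ({model.profile_kind!r})"
        )
    if K is not None and K != model.max_lag:
        raise ModelError(f"max_lag {K} does not match model ({model.max_lag})")
    if dim != model.dim:
        raise ModelError(f"profile dimension {dim} does not match model ({model.dim})")


def score_many(model: TrainedModel, profiles) -> np.ndarray:
    """Signed classification scores for a batch of profiles."""
    X, kind, K = _stack(profiles, None, None)
    _check_profile(model, kind, K, X.shape[1])
    if model.classifier_kind == "linear-svm":
        Xs = (X - model.scaler_mean) / model.scaler_scale
        return Xs @ model.weights + model.bias
    d_cod = np.linalg.norm(X - model.centroid_coding, axis=1)
    d_non = np.linalg.norm(X - model.centroid_noncoding, axis=1)
    return d_non - d_cod


def score(model: TrainedModel, profile) -> float:
    """Signed score of a single profile (positive ⇒ coding)."""
    if isinstance(profile, ProfileVector):
        return float(score_many(model, [profile])[0])
    return float(score_many(model, np.atleast_2d(profile))[0])


def predict(scores, threshold: float = 0.0) -> np.ndarray:
    """Labels from scores: coding (1) iff score > threshold, strictly."""
    return (np.asarray(scores, dtype=float) > threshold).astype(int)


# ---------------------------------------------------------------------------
# serialization


def _arr(a):
    return None if a is None else np.asarray(a).tolist()


def save_model(model: TrainedModel, path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "classifier_kind": model.classifier_kind,
        "profile_kind": model.profile_kind,
        "max_lag": model.max_lag,
        "species_id": model.species_id,
        "weights": _arr(model.weights),
        "bias": model.bias,
        "scaler_mean": _arr(model.scaler_mean),
        "scaler_scale": _arr(model.scaler_scale),
        "centroid_coding": _arr(model.centroid_coding),
        "centroid_noncoding": _arr(model.centroid_noncoding),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> TrainedModel:
    d = json.loads(Path(path).read_text())
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelError(f"unsupported model format {d.get('format_version')!r}")

    def arr(key):
        v = d.get(key)
        return None if v is None else np.asarray(v, dtype=float)

    return TrainedModel(
        d["classifier_kind"], d["profile_kind"], d["max_lag"], d["species_id"],
        weights=arr("weights"), bias=d["bias"],
        scaler_mean=arr("scaler_mean"), scaler_scale=arr("scaler_scale"),
        centroid_coding=arr("centroid_coding"),
        centroid_noncoding=arr("centroid_noncoding"),
    )
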