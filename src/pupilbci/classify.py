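"""LDA classification and EEG + pupil feature fusion.

Three feature modes feed the same linear discriminant:

- ``eeg``: the 2m CSP log-variance features (length 6 at the default m=3);
- ``pupil``: the single baselined trial-mean diameter;
- ``eeg_pupil``: the CSP vector with the pupil mean appended as one extra
  dimension (length 2m + 1) — the multimodal fusion this package exists for.

The discriminant assumes equal class covariances and equal priors (the
trial design is balanced), so the decision boundary sits at the midpoint of
the projected class means.  A score of exactly zero is called rest: a
mental switch should not fire on ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "FeatureVector",
    "LDAModel",
    "SingularCovarianceError",
    "fuse_features",
    "fit_lda",
    "predict_lda",
]

_CLASSES = ("nothing", "left")  # index 0 = rest, 1 = imagery


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance is singular; refit with shrinkage > 0."""


@dataclass
class FeatureVector:
    """One trial's classifier input."""

    values: np.ndarray
    mode: str  # eeg | pupil | eeg_pupil
    trial_ref: object = None
    pupil_imputed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class LDAModel:
    """Fitted linear discriminant: score = weights . x + bias, left iff > 0."""

    weights: np.ndarray
    bias: float
    class_means: dict
    pooled_covariance: np.ndarray
    feature_mode: str = "eeg"
    shrinkage: float | None = None


def fuse_features(csp_vector, pupil_mean: float) -> FeatureVector:
    """Append the baselined mean pupil diameter to a CSP feature vector.

    The EEG feature order is preserved; the pupil value becomes the last
    element, in mm (not standardized — its natural scale is already the
    baselined task-evoked response).  A non-finite pupil value (unusable
    trial) is imputed with 0.0, the baseline-neutral value, and flagged.
    """
    csp_vector = np.asarray(csp_vector, dtype=float).ravel()
    if csp_vector.size == 0:
        raise ValueError("fusion requires a non-empty EEG feature vector")
    imputed = not np.isfinite(pupil_mean)
    value = 0.0 if imputed else float(pupil_mean)
    return FeatureVector(
        values=np.append(csp_vector, value),
        mode="eeg_pupil",
        pupil_imputed=imputed,
    )


def _as_matrix(feature_vectors) -> np.ndarray:
    rows = [
        fv.values if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float).ravel()
        for fv in feature_vectors
    ]
    return np.vstack(rows)


def fit_lda(
    feature_vectors,
    labels,
    shrinkage: float | None = None,
    feature_mode: str = "eeg",
) -> LDAModel:
    """Fit the two-class linear discriminant with equal priors.

    ``shrinkage`` in [0, 1] blends the pooled covariance toward its
    diagonal ("auto" uses Ledoit-Wolf); with None/0 a plain LDA is fit and
    a singular pooled covariance raises :class:`SingularCovarianceError`.
    """
    x = _as_matrix(feature_vectors)
    y = np.asarray([str(l) for l in labels])
    present = set(y)
    if not {"left", "nothing"} <= present:
        raise ValueError(f"both classes required for training, got {sorted(present)}")
    if x.shape[0] < x.shape[1] + 2:
        import warnings

        warnings.warn(
            f"only {x.shape[0]} samples for {x.shape[1]} features; "
            "consider shrinkage",
            stacklevel=2,
        )
    mu = {c: x[y == c].mean(axis=0) for c in _CLASSES}
    scatter = sum(
        (x[y == c] - mu[c]).T @ (x[y == c] - mu[c]) for c in _CLASSES
    )
    pooled = np.atleast_2d(scatter / max(x.shape[0] - 2, 1))

    plain = shrinkage in (None, 0, 0.0)
    if plain and np.linalg.cond(pooled) > 1e12:
        raise SingularCovarianceError(
            "pooled covariance is singular; refit with shrinkage > 0 "
            "(e.g. shrinkage='auto')"
        )
    clf = LinearDiscriminantAnalysis(
        solver="lsqr",
        shrinkage=None if plain else shrinkage,
        priors=[0.5, 0.5],
    )
    clf.fit(x, y)
    # binary fit: decision_function is positive for classes_[1];
    # orient the score so positive means "left"
    sign = 1.0 if clf.classes_[1] == "left" else -1.0
    w = sign * clf.coef_[0]
    # recompute the bias from the class means so the boundary sits exactly
    # at their projected midpoint (equal priors; robust to solver round-off)
    b = -float(w @ ((mu["left"] + mu["nothing"]) / 2.0))
    return LDAModel(
        weights=np.asarray(w, dtype=float).ravel(),
        bias=float(b),
        class_means={c: mu[c] for c in _CLASSES},
        pooled_covariance=pooled,
        feature_mode=feature_mode,
        shrinkage=None if plain else shrinkage,
    )


def predict_lda(model: LDAModel, feature_vector, return_score: bool = False):
    """Classify one feature vector (or a batch, row-wise).

    score = weights . x + bias; "left" iff score > 0, rest otherwise
    (exact zero -> rest).
    """
    x = (
        feature_vector.values
        if isinstance(feature_vector, FeatureVector)
        else np.asarray(feature_vector, dtype=float)
    )
    if x.ndim == 2:
        out = [predict_lda(model, row, return_score) for row in x]
        return out
    if x.size != model.weights.size:
        raise ValueError(
            f"feature dimension {x.size} does not match model ({model.weights.size})"
        )
    score = float(model.weights @ x + model.bias)
    label = "left" if score > 0 else "nothing"
    return (label, score) if return_score else label
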