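r"""Common Spatial Patterns for two-class motor-imagery discrimination.

CSP finds spatial filters (linear channel combinations) whose output
variance is maximal for one class and minimal for the other, by
simultaneously diagonalizing the two class-mean covariance matrices:

1. Per-trial normalized spatial covariance  C = E E' / trace(E E'),
   averaged within class to give C̄_l (left imagery) and C̄_nt (no task).
2. Composite covariance  C_c = C̄_nt + C̄_l, eigendecomposed
   C_c = U_c λ_c U_c' with eigenvalues sorted descending.
3. Whitening  P = λ_c^{-1/2} U_c', so that P C_c P' = I.  (The inverse
   square root is required for whitening; using λ_c^{-1} would scale the
   whitened composite to the identity squared inverse, not the identity.)
4. The whitened class covariances S_nt = P C̄_nt P' and S_l = P C̄_l P'
   share eigenvectors B, and their eigenvalue pairs sum to one
   (λ_nt + λ_l = I): a direction maximally expressed at rest is minimally
   expressed during imagery and vice versa.
5. Projection matrix  W = B' P  (rows are spatial filters); a single trial
   decomposes as Z = W E.  The columns of W^{-1} (pseudo-inverse on the
   retained subspace) are the spatial *patterns* — source scalp
   topographies suitable for plotting.

Feature extraction keeps the m top and m bottom filters (by λ_nt) and
returns log-normalized variances of the projected trial, the standard
companion to an LDA classifier.

Common-average-referenced EEG is rank deficient (rank <= N-1); a small
diagonal shrinkage plus discarding near-null whitened dimensions repairs
this without distorting the discriminative subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "CovarianceEstimate",
    "SpatialFilterModel",
    "RankDeficiencyError",
    "spatial_covariance",
    "mean_covariance",
    "fit_csp",
    "csp_features",
    "pattern_table",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Composite covariance is rank deficient beyond regularization capacity."""


@dataclass
class CovarianceEstimate:
    """A normalized spatial covariance (unit trace before averaging)."""

    matrix: np.ndarray
    n_trials: int
    class_label: str | None = None


@dataclass
class SpatialFilterModel:
    """Fitted CSP model.

    W : full projection matrix, filters x channels (rows are filters).
    selected_filters : 2m row indices of W (m top + m bottom by lambda_nt).
    patterns : channels x filters; columns are scalp topographies
        (pseudo-inverse of W on the retained subspace).
    lambda_nt, lambda_l : paired eigenvalues, sorted descending in
        lambda_nt; lambda_nt + lambda_l == 1 elementwise.
    m : retained filter pairs.
    whitener : P with P C_c P' = I on the retained subspace.
    eigvecs_b : common eigenvector matrix B of the whitened class
        covariances.
    """

    W: np.ndarray
    selected_filters: np.ndarray
    patterns: np.ndarray
    lambda_nt: np.ndarray
    lambda_l: np.ndarray
    m: int
    whitener: np.ndarray
    eigvecs_b: np.ndarray
    channel_labels: list[str] | None = None
    log_variance: bool = True

    @property
    def n_features(self) -> int:
        return 2 * self.m


def spatial_covariance(eeg_epoch: np.ndarray) -> CovarianceEstimate:
    """Normalized spatial covariance of one epoch: C = E E' / trace(E E').

    Trace-normalization makes C invariant to epoch-wide amplitude scaling,
    so trials with different overall signal power contribute equally.
    """
    e = np.asarray(eeg_epoch, dtype=float)
    if e.ndim != 2:
        raise ValueError("epoch must be a channels x samples matrix")
    prod = e @ e.T
    tr = np.trace(prod)
    if tr <= 0:
        raise ValueError("all-zero epoch: covariance trace is zero")
    return CovarianceEstimate(matrix=prod / tr, n_trials=1)


def mean_covariance(epochs, class_label: str | None = None) -> CovarianceEstimate:
    """Class-mean covariance: average of per-trial normalized covariances."""
    epochs = list(epochs)
    if not epochs:
        raise ValueError("no epochs to average")
    mats = [spatial_covariance(e).matrix for e in epochs]
    return CovarianceEstimate(matrix=np.mean(mats, axis=0),
                              n_trials=len(mats), class_label=class_label)


def _sorted_eigh(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition, eigenvalues descending; ties keep the
    original (ascending-index) order via a stable sort."""
    vals, vecs = scipy.linalg.eigh(a)
    order = np.argsort(-vals, kind="stable")
    return vals[order], vecs[:, order]


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: largest-magnitude component positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def fit_csp(
    trials_left,
    trials_nothing,
    m: int = 3,
    regularization: float = 1e-6,
    null_tol: float = 1e-9,
    channel_labels: list[str] | None = None,
    log_variance: bool = True,
) -> SpatialFilterModel:
    """Fit CSP from per-class epoch lists (each epoch channels x samples).

    Parameters
    ----------
    m : filter pairs to retain (default 3 -> 6 features).
    regularization : diagonal shrinkage epsilon; each class covariance gets
        ``eps * trace/N * I`` before the composite is formed.
    null_tol : whitened dimensions with composite eigenvalue below
        ``null_tol * max`` are discarded (CAR guarantees at least one).
    """
    left = list(trials_left)
    nothing = list(trials_nothing)
    if len(left) < 2 or len(nothing) < 2:
        raise ValueError("need at least 2 trials per class to fit CSP")
    n = left[0].shape[0]
    if any(e.shape[0] != n for e in left + nothing):
        raise ValueError("all epochs must share the channel count")

    c_l = mean_covariance(left, "left").matrix
    c_nt = mean_covariance(nothing, "nothing").matrix
    eye = np.eye(n)
    reg_floor = regularization * (np.trace(c_l) + np.trace(c_nt)) / n
    c_l = c_l + regularization * np.trace(c_l) / n * eye
    c_nt = c_nt + regularization * np.trace(c_nt) / n * eye
    c_c = c_nt + c_l

    lam_c, u_c = _sorted_eigh(c_c)
    # directions whose composite variance sits at the shrinkage floor carry
    # no signal (the CAR null space lands exactly there); drop them
    keep = lam_c > max(null_tol * lam_c[0], 10.0 * reg_floor)
    k = int(keep.sum())
    if k < 2 * m:
        raise RankDeficiencyError(
            f"composite covariance has only {k} usable dimensions "
            f"({n - k} deficient) — fewer than the 2*m = {2 * m} requested "
            f"filters; increase regularization or reduce m"
        )
    # whitening: inverse square root of the composite spectrum
    p = (u_c[:, keep] / np.sqrt(lam_c[keep])).T  # (k, n)

    s_nt = p @ c_nt @ p.T
    lam_nt, b = _sorted_eigh(s_nt)  # descending in the no-task class
    b = _fix_signs(b)
    lam_nt = np.clip(lam_nt, 0.0, 1.0)
    lam_l = 1.0 - lam_nt

    w = b.T @ p  # (k, n) rows are filters
    patterns = np.linalg.pinv(w)  # (n, k) columns are topographies
    selected = np.concatenate([np.arange(m), np.arange(k - m, k)])
    return SpatialFilterModel(
        W=w,
        selected_filters=selected,
        patterns=patterns,
        lambda_nt=lam_nt,
        lambda_l=lam_l,
        m=m,
        whitener=p,
        eigvecs_b=b,
        channel_labels=channel_labels,
        log_variance=log_variance,
    )


def csp_features(
    model: SpatialFilterModel,
    eeg_epoch: np.ndarray,
    eps: float = 1e-15,
) -> np.ndarray:
    """Variance features of one epoch under the 2m selected filters.

    Projects Z = W_sel E, takes the per-filter variance and (by default)
    the normalized log transform f_p = log(var_p / sum_q var_q).  The ratio
    cancels epoch-wide amplitude scale; exp(f) sums to one.  Zero-variance
    projections are floored at ``eps`` times the total before the log.
    """
    e = np.asarray(eeg_epoch, dtype=float)
    if e.shape[0] != model.W.shape[1]:
        raise ValueError(
            f"epoch has {e.shape[0]} channels, model expects {model.W.shape[1]}"
        )
    z = model.W[model.selected_filters] @ e
    var = z.var(axis=1)
    total = var.sum()
    if total <= 0:
        raise ValueError("epoch has zero variance under all selected filters")
    if model.log_variance:
        return np.log(np.maximum(var, eps * total) / total)
    return var / total


def pattern_table(model: SpatialFilterModel, path=None):
    """Scalp-topography export: one row per channel, one column per selected
    pattern (named by its no-task eigenvalue), suitable for topographic
    plotting.  Written as tab-delimited text when ``path`` is given."""
    import pandas as pd

    labels = model.channel_labels or [
        f"ch{i}" for i in range(model.patterns.shape[0])]
    cols = {"channel": labels}
    for rank, idx in enumerate(model.selected_filters):
        name = f"pattern_{rank}_lnt_{model.lambda_nt[idx]:.3f}"
        cols[name] = model.patterns[:, idx]
    df = pd.DataFrame(cols)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
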