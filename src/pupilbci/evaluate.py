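r"""Evaluation protocols and performance / association metrics.

Performance of the two-class switch is summarized by three numbers:

* accuracy  P = (TP + TN) / N_total;
* the Wolpaw information transfer rate per trial,
  B = log2 N + P log2 P + (1 - P) log2((1 - P)/(N - 1)),
  with N the number of targets (2 here) and 0*log 0 = 0; bits/min scales B
  by trials per minute (the 6 s active trial -> 10 trials/min);
* Cohen's kappa  k = (P - P0)/(1 - P0) with chance level P0 = 1/N for the
  balanced design.

Two training protocols are provided: stratified k-fold cross-validation
within one block, and cross-block transfer (fit on one block, test on the
other — the harder, non-stationary case).

Association between the predictive power of the two modalities is measured
by Pearson correlation and by a histogram plug-in mutual-information
estimate (bits), with Freedman-Diaconis binning and a permutation z-score.
The BCI-illiteracy analysis splits subjects at the lower quartile of
EEG-only accuracy and compares EEG vs fused accuracy with a paired t test
and Cohen's d within each subgroup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .pipeline import Pipeline, PipelineConfig
from .session import Trial

__all__ = [
    "EvalReport",
    "AssociationReport",
    "SubgroupReport",
    "LeakageError",
    "performance_metrics",
    "confusion_counts",
    "itr_bits_per_trial",
    "cohen_kappa",
    "crossval_within_block",
    "cross_block",
    "mutual_information",
    "pearson_association",
    "subgroup_compare",
    "evaluate_subject",
    "evaluate_cohort",
    "write_report_grid",
]


class LeakageError(ValueError):
    """Train and test trials overlap."""


@dataclass
class EvalReport:
    """Per-method, per-protocol performance summary."""

    method: str
    protocol: str
    accuracy: float
    kappa: float
    itr_bits_per_trial: float
    itr_bits_per_min: float
    tp: int
    tn: int
    fp: int
    fn: int
    n_trials: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AssociationReport:
    """Mutual-information estimate with permutation calibration."""

    mutual_information: float  # bits
    h_x: float
    h_y: float
    h_joint: float
    permutation_z: float
    n_bins: int
    n_permutations: int


@dataclass
class SubgroupReport:
    """Paired comparison of EEG vs hybrid accuracy within one subgroup."""

    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float | None
    df: int
    p: float | None
    cohen_d: float | None
    degenerate: bool = False


# -- scalar metrics ------------------------------------------------------


def itr_bits_per_trial(p: float, n_classes: int = 2) -> float:
    """Wolpaw bits per trial; 0*log2(0) taken as 0."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("accuracy must be in [0, 1]")
    if n_classes < 2:
        raise ValueError("need at least 2 targets")
    b = np.log2(n_classes)
    if p > 0:
        b += p * np.log2(p)
    if p < 1:
        b += (1.0 - p) * np.log2((1.0 - p) / (n_classes - 1))
    return float(b)


def cohen_kappa(p: float, p0: float) -> float:
    """Chance-corrected agreement (P - P0)/(1 - P0)."""
    if p0 >= 1.0:
        raise ValueError("chance level must be < 1")
    return float((p - p0) / (1.0 - p0))


def confusion_counts(true_labels, predicted_labels,
                     positive: str = "left") -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with "left" (imagery) as the positive class."""
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted_labels, strict=True):
        if t == positive:
            tp += p == positive
            fn += p != positive
        else:
            tn += p != positive
            fp += p == positive
    return int(tp), int(tn), int(fp), int(fn)


def performance_metrics(
    tp: int, tn: int, fp: int, fn: int,
    n_classes: int = 2,
    trial_seconds: float = 6.0,
    method: str = "eeg",
    protocol: str = "cv_within_block",
) -> EvalReport:
    """Build the full report from confusion counts.

    ``trial_seconds`` is the active trial duration used for the bits/min
    conversion (6 s -> 10 trials per minute).
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n_total = tp + tn + fp + fn
    if n_total == 0:
        raise ValueError("no trials in confusion counts")
    p = (tp + tn) / n_total
    b = itr_bits_per_trial(p, n_classes)
    return EvalReport(
        method=method,
        protocol=protocol,
        accuracy=float(p),
        kappa=cohen_kappa(p, 1.0 / n_classes),
        itr_bits_per_trial=b,
        itr_bits_per_min=b * 60.0 / trial_seconds,
        tp=tp, tn=tn, fp=fp, fn=fn,
        n_trials=n_total,
    )


# -- protocols -----------------------------------------------------------


def crossval_within_block(
    trials: list[Trial],
    config: PipelineConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation within one block.

    The whole pipeline (CSP, LDA, pupil threshold) is refit on each
    training split; the confusion counts are pooled over the k test folds,
    so every trial is scored exactly once.
    """
    config = config or PipelineConfig()
    labels = np.array([t.class_label for t in trials])
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("both classes required")
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smaller class count ({counts.min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    true_all, pred_all = [], []
    for train_idx, test_idx in skf.split(np.zeros(len(trials)), labels):
        pipe = Pipeline(config).fit([trials[i] for i in train_idx])
        preds = pipe.predict([trials[i] for i in test_idx])
        true_all.extend(labels[test_idx])
        pred_all.extend(preds)
    tp, tn, fp, fn = confusion_counts(true_all, pred_all)
    return performance_metrics(tp, tn, fp, fn, method=config.mode,
                               protocol="cv_within_block")


def cross_block(
    train_trials: list[Trial],
    test_trials: list[Trial],
    config: PipelineConfig | None = None,
) -> EvalReport:
    """Fit on one block in its entirety, report on the other block only."""
    config = config or PipelineConfig()
    train_ids = {id(t) for t in train_trials}
    if train_ids & {id(t) for t in test_trials}:
        raise LeakageError("train and test share trial objects")
    train_blocks = {t.block_id for t in train_trials}
    if train_blocks & {t.block_id for t in test_trials}:
        raise LeakageError(
            f"train and test share block ids {sorted(train_blocks)}")
    pipe = Pipeline(config).fit(train_trials)
    preds = pipe.predict(test_trials)
    tp, tn, fp, fn = confusion_counts(
        [t.class_label for t in test_trials], preds)
    return performance_metrics(tp, tn, fp, fn, method=config.mode,
                               protocol="cross_block")


# -- association ---------------------------------------------------------


def _fd_bin_count(x: np.ndarray) -> int:
    edges = np.histogram_bin_edges(x, bins="fd")
    return max(len(edges) - 1, 1)


def mutual_information(
    x_samples,
    y_samples,
    bins: int | None = None,
    n_permutations: int = 200,
    seed: int = 0,
) -> AssociationReport:
    """Histogram plug-in mutual information in bits, with permutation z.

    Bin count per axis defaults to the Freedman-Diaconis rule computed on
    each variable, taking the maximum so both axes share one count
    (override with ``bins``).  The permutation z-score shuffles the pairing
    and standardizes the observed MI against the null distribution:
    z = (MI_obs - mean_perm) / sd_perm.
    """
    x = np.asarray(x_samples, dtype=float).ravel()
    y = np.asarray(y_samples, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 8:
        raise ValueError("need at least 8 paired samples")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant input: mutual information is 0", stacklevel=2)
        h = 0.0
        return AssociationReport(0.0, h, h, h, 0.0, 1, 0)
    if bins is None:
        bins = max(_fd_bin_count(x), _fd_bin_count(y))

    def _entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    def _mi(counts: np.ndarray) -> tuple[float, float, float, float]:
        p = counts / counts.sum()
        hx = _entropy(p.sum(axis=1))
        hy = _entropy(p.sum(axis=0))
        hj = _entropy(p.ravel())
        return hx + hy - hj, hx, hy, hj

    joint, ex, ey = np.histogram2d(x, y, bins=bins)
    mi_obs, hx, hy, hj = _mi(joint)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm, _, _ = np.histogram2d(x, rng.permutation(y), bins=[ex, ey])
        null[i] = _mi(perm)[0]
    sd = null.std()
    z = float((mi_obs - null.mean()) / sd) if sd > 0 else float("inf")
    return AssociationReport(
        mutual_information=float(mi_obs),
        h_x=hx, h_y=hy, h_joint=hj,
        permutation_z=z,
        n_bins=int(bins),
        n_permutations=n_permutations,
    )


def pearson_association(acc_a, acc_b) -> tuple[float, float]:
    """Pearson r between paired per-participant accuracies, with the
    two-sided p value from the t transform."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one of the accuracy vectors")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


def subgroup_compare(
    acc_eeg,
    acc_hybrid,
    quartile_fraction: float = 0.25,
) -> dict[str, SubgroupReport]:
    """Lower-quartile (potential BCI illiterate) vs upper subgroup analysis.

    Splits participants at the ``quartile_fraction`` quantile of the
    EEG-only accuracy; within each subgroup, the paired difference
    hybrid - EEG is tested with a paired t (and Cohen's
    d = mean(diff)/sd(diff)).  Zero-variance differences are flagged
    degenerate instead of reporting a t statistic.
    """
    a = np.asarray(acc_eeg, dtype=float)
    b = np.asarray(acc_hybrid, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors required")
    cut = np.quantile(a, quartile_fraction)
    out: dict[str, SubgroupReport] = {}
    for name, mask in (("lower", a <= cut), ("upper", a > cut)):
        if mask.sum() < 2:
            raise ValueError(f"subgroup {name!r} has fewer than 2 participants")
        da, db = a[mask], b[mask]
        diff = db - da
        sd_diff = diff.std(ddof=1)
        if sd_diff == 0:
            if np.allclose(diff, 0):
                t = 0.0
                p = 1.0
                d = 0.0
                degen = False
            else:
                t = p = d = None
                degen = True
        else:
            t_stat, p_val = sps.ttest_rel(db, da)
            t, p = float(t_stat), float(p_val)
            d = float(diff.mean() / sd_diff)
            degen = False
        out[name] = SubgroupReport(
            n=int(mask.sum()),
            mean_a=float(da.mean()), sd_a=float(da.std(ddof=1)),
            mean_b=float(db.mean()), sd_b=float(db.std(ddof=1)),
            t=t, df=int(mask.sum() - 1), p=p, cohen_d=d, degenerate=degen,
        )
    return out


# -- subject / cohort drivers -------------------------------------------


def evaluate_subject(
    block_trials: list[list[Trial]],
    config: PipelineConfig,
    protocol: str = "cv_within_block",
    k: int = 10,
    seed: int = 0,
) -> float:
    """One subject's accuracy under one protocol and feature mode.

    cv_within_block: k-fold CV per block, accuracies averaged over blocks.
    cross_block: fit on each block, test on the other, both directions
    averaged.
    """
    if protocol == "cv_within_block":
        accs = [crossval_within_block(b, config, k=k, seed=seed).accuracy
                for b in block_trials]
        return float(np.mean(accs))
    if protocol == "cross_block":
        if len(block_trials) < 2:
            raise ValueError("cross_block needs two blocks")
        accs = [cross_block(block_trials[0], block_trials[1], config).accuracy,
                cross_block(block_trials[1], block_trials[0], config).accuracy]
        return float(np.mean(accs))
    raise ValueError(f"unknown protocol {protocol!r}")


def evaluate_cohort(
    cohort_block_trials: list[list[list[Trial]]],
    base_config: PipelineConfig | None = None,
    methods: tuple[str, ...] = ("pupil", "eeg", "eeg_pupil"),
    protocols: tuple[str, ...] = ("cv_within_block", "cross_block"),
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject accuracy grid: one row per subject, one column per
    (method, protocol) pair."""
    base = (base_config or PipelineConfig()).to_dict()
    rows = []
    for blocks in cohort_block_trials:
        row = {}
        for method in methods:
            cfg = PipelineConfig.from_dict({**base, "mode": method})
            for protocol in protocols:
                row[f"{method}/{protocol}"] = evaluate_subject(
                    blocks, cfg, protocol=protocol, k=k, seed=seed)
        rows.append(row)
    return pd.DataFrame(rows)


def write_report_grid(reports: list[EvalReport], path) -> pd.DataFrame:
    """Write a per-method x per-protocol grid (accuracy, kappa, ITR) as
    delimited text; returns the DataFrame written."""
    df = pd.DataFrame([r.to_dict() for r in reports])
    path = str(path)
    if path.endswith(".json"):
        df.to_json(path, orient="records", indent=1)
    else:
        df.to_csv(path, sep="\t", index=False)
    return df
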