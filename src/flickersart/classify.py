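"""Per-trial feature tables and RBF-SVM state decoding.

A participant's labeled trials become rows of a feature table: single-trial
ERP triples (W, t, s) for P1/N1 at P7 and P8 and P3 at Fz and Pz,
filter–Hilbert alpha and theta power at P7/P8/Fz/Pz over the pre- and
post-stimulus intervals, and — in the with-SSVEP variant — per-trial ERSP
band-window means at the flicker fundamental (12–13 Hz) and harmonic
(24.5–25.5 Hz).

Decoding reproduces the study's protocol literally: a stratified 70/30
train/test split; z-scoring of the training and testing sets each with its
own column statistics; 10-fold cross-validated grid search over an RBF-SVM's
(C, sigma) with minority-class oversampling applied inside each training
fold only; evaluation on the untouched test set with accuracy, sensitivity
and specificity; and a binomial corrected chance level
St(α) = binoinv(1−α, n, 1/c) · 100 / n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from . import erp as erp_mod
from . import spectral, timefreq
from .containers import EmptyClassError, EpochSet, TrialLabels

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierReport",
    "build_feature_table",
    "split_stratified",
    "zscore_train_test",
    "oversample",
    "train_svm",
    "evaluate",
    "corrected_chance",
    "run_classification",
    "POSITIVE_LABELS",
]

#: the state of interest per labeling (reported as "sensitivity")
POSITIVE_LABELS = {"stickiness": "more_sticky", "attention": "mind_wandering"}

SIGMA_RANGE = (0.001, 10.0)
C_RANGE = (1e-5, 0.1)
TUNE_LENGTH = 9


@dataclass
class ClassifierReport:
    """Decoding outcome for one participant and one feature-set variant."""

    accuracy: float
    sensitivity: float
    specificity: float
    C: float
    sigma: float
    cv_accuracy: float
    n_train: int
    n_test: int
    corrected_chance: float
    positive_label: str
    with_ssvep: bool
    seed: int


# --------------------------------------------------------------------------
# feature assembly
# --------------------------------------------------------------------------

def build_feature_table(
    epochs_erp: EpochSet,
    epochs_tf: EpochSet,
    labels: TrialLabels,
    target: str = "stickiness",
    with_ssvep: bool = True,
    tf_result: Optional[timefreq.TFResult] = None,
    scale_grid: Sequence[float] = erp_mod.DEFAULT_SCALE_GRID,
) -> pd.DataFrame:
    """Assemble the per-trial feature table for one labeling target.

    Rows are the trials whose label is not ``excluded``; the class goes into
    the ``label`` column. ``tf_result`` (Morlet coefficients at Oz over the
    −500..1300 ms epochs) may be passed to avoid recomputation; it is only
    needed when ``with_ssvep`` is true.
    """
    if target not in POSITIVE_LABELS:
        raise ValueError("target must be 'stickiness' or 'attention'")
    lab = (
        labels.stickiness_class if target == "stickiness" else labels.attention_state
    )
    keep = np.flatnonzero(lab != "excluded")
    if keep.size == 0:
        raise EmptyClassError("no labeled trials for this target")

    cols: Dict[str, np.ndarray] = {}

    # single-trial ERP features on the -200..900 ms segments
    for comp, spec in erp_mod.COMPONENT_SPECS.items():
        for electrode in spec.electrodes:
            data = epochs_erp.get_channel(electrode)
            W = np.empty(keep.size)
            T = np.empty(keep.size)
            S = np.empty(keep.size)
            for j, tr in enumerate(keep):
                feat = erp_mod.single_trial_erp(
                    data[tr], epochs_erp.times, spec, epochs_erp.fs, scale_grid
                )
                W[j], T[j], S[j] = feat.W, feat.t, feat.s
            base = f"{comp}_{electrode}"
            cols[f"{base}_W"] = W
            cols[f"{base}_t"] = T
            cols[f"{base}_s"] = S

    # filter-Hilbert band power on the -500..1300 ms epochs
    for electrode in spectral.POWER_ELECTRODES:
        for band in spectral.BANDS:
            for name, window in spectral.INTERVALS.items():
                p = spectral.band_power(epochs_tf, band, electrode, window)
                cols[f"{band}_{electrode}_{name}"] = p[keep]

    # SSVEP features: per-trial ERSP band-window means at Oz
    if with_ssvep:
        if tf_result is None:
            tf_result = timefreq.morlet_decompose(
                epochs_tf, electrode="Oz", compute_maps=False
            )
        for tag, f_range in (
            ("ersp_12_5Hz", timefreq.FUNDAMENTAL_RANGE),
            ("ersp_25Hz", timefreq.HARMONIC_RANGE),
        ):
            vals = timefreq.single_trial_band_window_mean(
                tf_result.coeffs, tf_result.freqs, tf_result.times, f_range
            )
            cols[tag] = vals[keep]

    table = pd.DataFrame(cols)
    table["label"] = lab[keep]
    if table.isna().any().any():
        raise ValueError("feature table contains missing values")
    return table


# --------------------------------------------------------------------------
# protocol steps
# --------------------------------------------------------------------------

def split_stratified(
    table: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split preserving the class mix within 1 trial."""
    y = table["label"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise EmptyClassError("both classes must be present to split")
    if counts.min() < 2:
        raise EmptyClassError(
            f"class {classes[np.argmin(counts)]!r} has < 2 trials"
        )
    train, test = train_test_split(
        table,
        train_size=train_fraction,
        stratify=y,
        random_state=seed % (2**32),
        shuffle=True,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def zscore_train_test(
    train: pd.DataFrame, test: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize each set with its own column means and sds.

    This mirrors the study's stated normalization (test-set-own statistics),
    not the conventional train-statistics transform. Columns with zero
    variance in either set are dropped from both with a warning.
    """
    feat_cols = [c for c in train.columns if c != "label"]
    drop = []
    for c in feat_cols:
        if train[c].std(ddof=0) == 0 or test[c].std(ddof=0) == 0:
            drop.append(c)
    if drop:
        logger.warning("dropping zero-variance feature columns: %s", drop)
    keep = [c for c in feat_cols if c not in drop]

    def _z(df: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=df.index)
        for c in keep:
            x = df[c].to_numpy(dtype=float)
            out[c] = (x - x.mean()) / x.std(ddof=0)
        out["label"] = df["label"].to_numpy()
        return out

    return _z(train), _z(test)


def oversample(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Duplicate minority-class rows (with replacement) to a 1:1 class ratio."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("oversample needs both classes present")
    if classes.size != 2:
        raise ValueError("binary classification only")
    n_target = counts.max()
    X_parts, y_parts = [X], [y]
    for cls, cnt in zip(classes, counts):
        if cnt < n_target:
            idx = np.flatnonzero(y == cls)
            extra = rng.choice(idx, size=n_target - cnt, replace=True)
            X_parts.append(X[extra])
            y_parts.append(y[extra])
    return np.concatenate(X_parts), np.concatenate(y_parts)


def _param_grid() -> Tuple[np.ndarray, np.ndarray]:
    sigmas = np.logspace(
        math.log10(SIGMA_RANGE[0]), math.log10(SIGMA_RANGE[1]), TUNE_LENGTH
    )
    Cs = np.logspace(math.log10(C_RANGE[0]), math.log10(C_RANGE[1]), TUNE_LENGTH)
    return Cs, sigmas


def train_svm(
    train: pd.DataFrame,
    cv_folds: int = 10,
    seed: int = 0,
) -> Tuple[SVC, float, float, float]:
    """Grid-search an RBF-SVM with in-fold oversampling; refit on all of train.

    The grid is ``TUNE_LENGTH`` log-spaced values of C in [1e-5, 0.1] and of
    the kernel width sigma (sklearn's ``gamma``) in [0.001, 10]. Folds are
    stratified; the minority class is oversampled within each fold's training
    part only, never in the validation part. Returns
    (fitted model, C, sigma, best CV accuracy). Ties prefer smaller C, then
    smaller sigma (simpler, smoother models).
    """
    feat_cols = [c for c in train.columns if c != "label"]
    X = train[feat_cols].to_numpy(dtype=float)
    y = train["label"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("binary classification only")
    n_folds = min(cv_folds, int(counts.min()))
    if n_folds < 2:
        raise EmptyClassError("too few trials per class for cross-validation")
    if n_folds < cv_folds:
        logger.warning(
            "reducing CV folds from %d to %d (smallest class has %d trials)",
            cv_folds,
            n_folds,
            counts.min(),
        )
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    folds = list(skf.split(X, y))
    # pre-draw per-fold oversampling so every grid point sees the same folds
    fold_data = []
    for tr_idx, va_idx in folds:
        Xb, yb = oversample(X[tr_idx], y[tr_idx], rng)
        fold_data.append((Xb, yb, X[va_idx], y[va_idx]))

    Cs, sigmas = _param_grid()
    best = None  # (acc, -C, -sigma) maximized -> ties prefer small C, sigma
    for C in Cs:
        for sigma in sigmas:
            accs = []
            for Xb, yb, Xv, yv in fold_data:
                model = SVC(C=C, kernel="rbf", gamma=sigma)
                model.fit(Xb, yb)
                accs.append(float(np.mean(model.predict(Xv) == yv)))
            acc = float(np.mean(accs))
            key = (acc, -C, -sigma)
            if best is None or key > best[0]:
                best = (key, C, sigma, acc)
    _, C_best, sigma_best, cv_acc = best
    Xb, yb = oversample(X, y, rng)
    final = SVC(C=C_best, kernel="rbf", gamma=sigma_best)
    final.fit(Xb, yb)
    return final, float(C_best), float(sigma_best), cv_acc


def evaluate(
    model: SVC,
    test: pd.DataFrame,
    positive_label: str,
) -> Tuple[float, float, float]:
    """Accuracy, sensitivity and specificity on the untouched test set.

    sensitivity = TP / (TP + FN) and specificity = TN / (TN + FP), with
    ``positive_label`` the class counted as positive.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    feat_cols = [c for c in test.columns if c != "label"]
    y = test["label"].to_numpy()
    pred = model.predict(test[feat_cols].to_numpy(dtype=float))
    pos = y == positive_label
    tp = int(np.sum(pos & (pred == positive_label)))
    fn = int(np.sum(pos & (pred != positive_label)))
    tn = int(np.sum(~pos & (pred != positive_label)))
    fp = int(np.sum(~pos & (pred == positive_label)))
    accuracy = float(np.mean(pred == y))
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return float(accuracy), float(sensitivity), float(specificity)


def corrected_chance(alpha: float, n: int, c: int = 2) -> float:
    """Binomial corrected chance level in percent.

    The smallest k whose Binomial(n, 1/c) CDF reaches 1 − alpha, as
    100·k/n: the lowest accuracy significantly above guessing at level
    alpha for n trials and c classes.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n < 1 or c < 2:
        raise ValueError("need n >= 1 and c >= 2")
    k = int(sps.binom.ppf(1.0 - alpha, n, 1.0 / c))
    return 100.0 * k / n


def run_classification(
    table: pd.DataFrame,
    target: str = "stickiness",
    with_ssvep: bool = True,
    alpha: float = 0.01,
    train_fraction: float = 0.7,
    cv_folds: int = 10,
    seed: int = 0,
) -> ClassifierReport:
    """Full per-participant protocol: split → z-score → tune → evaluate."""
    train, test = split_stratified(table, train_fraction, seed=seed)
    train_z, test_z = zscore_train_test(train, test)
    model, C, sigma, cv_acc = train_svm(train_z, cv_folds=cv_folds, seed=seed)
    positive = POSITIVE_LABELS[target]
    acc, sens, spec = evaluate(model, test_z, positive)
    return ClassifierReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        C=C,
        sigma=sigma,
        cv_accuracy=cv_acc,
        n_train=len(train_z),
        n_test=len(test_z),
        corrected_chance=corrected_chance(alpha, len(test_z)),
        positive_label=positive,
        with_ssvep=with_ssvep,
        seed=seed,
    )
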