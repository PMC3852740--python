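"""Localization statistics: accuracy threshold sweeps and the additive
building-block regression.

Two binary scoring schemes relate model predictions to observed staining:
(1) mitochondrial-or-lysosomal ("organelle") vs not, and (2) cytoplasmic
(or plasma) membrane vs not.  A compound is called positive when its
predicted percent mass in the relevant compartment(s) meets a threshold;
sweeping the threshold from 0 to 100% traces an accuracy curve,

    accuracy = (#correct) / (#correct + #incorrect) = (TP+TN)/(TP+FP+FN+TN),

and the "balanced" threshold is where the two per-class accuracies are
closest.

Independently, any per-compound image feature Y indexed by aldehyde i and
head j can be fit by the additive model f(Y) = A(i) + P(j) (f identity or
log), estimated by least squares under the identifiability constraint
sum_i A(i) = 0 with the intercept absorbed into P.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORGANELLE_SCHEME = "organelle"
MEMBRANE_SCHEME = "membrane"
_LABELS = ("organelle", "membrane", "nuclear")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class AccuracyCurve:
    thresholds: np.ndarray  # percent
    accuracy: np.ndarray
    per_class_accuracy_pos: np.ndarray
    per_class_accuracy_neg: np.ndarray
    balanced_threshold: float
    balanced_accuracy: float


@dataclass
class AdditiveFit:
    feature_name: str
    transform: str  # identity | log
    alpha: pd.Series  # per aldehyde index, sum-zero
    beta: pd.Series  # per head index, absorbs the intercept
    residuals: np.ndarray
    dropped_levels: dict = field(default_factory=dict)
    cv_scores: np.ndarray | None = None

    def predict(self, aldehyde, head):
        """Fitted value on the transformed scale for one design cell."""
        return float(self.alpha[aldehyde] + self.beta[head])


def assign_observed_category(label: str) -> tuple[bool, bool]:
    """Binary labels for the two scoring schemes.

    Scheme 1 is positive only for organelle (mitochondrial/lysosomal)
    staining; scheme 2 only for membrane staining; nuclear staining is
    negative in both.
    """
    if label not in _LABELS:
        raise ValueError(f"unknown staining label {label!r}")
    return label == "organelle", label == "membrane"


def confusion_at_threshold(
    predicted_fraction, observed, threshold: float
) -> ConfusionCounts:
    """Confusion counts calling positives at predicted fraction >= threshold.

    ``predicted_fraction`` is in percent; ``observed`` is the boolean
    observed-category membership.  Observed positives below threshold are
    counted as false negatives (standard convention).
    """
    pred = np.asarray(predicted_fraction, dtype=float)
    obs = np.asarray(observed, dtype=bool)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed lengths differ")
    call = pred >= threshold
    return ConfusionCounts(
        tp=int(np.sum(call & obs)),
        fp=int(np.sum(call & ~obs)),
        fn=int(np.sum(~call & obs)),
        tn=int(np.sum(~call & ~obs)),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """Fraction of correctly classified compounds, (TP+TN)/total."""
    if counts.total == 0:
        raise ValueError("accuracy undefined for zero compounds")
    return (counts.tp + counts.tn) / counts.total


def accuracy_sweep(
    predicted_fractions, observed, step: float = 1.0
) -> AccuracyCurve:
    """Accuracy as a function of the calling threshold over 0-100%.

    Per-class accuracies are TP/(TP+FN) and TN/(TN+FP); the balanced
    threshold minimizes their absolute difference (ties resolved to the
    lowest threshold) and the balanced accuracy is the overall accuracy
    there.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pred = np.asarray(predicted_fractions, dtype=float)
    obs = np.asarray(observed, dtype=bool)
    thresholds = np.arange(0.0, 100.0 + 0.5 * step, step)
    acc = np.empty_like(thresholds)
    acc_pos = np.empty_like(thresholds)
    acc_neg = np.empty_like(thresholds)
    n_pos, n_neg = int(obs.sum()), int((~obs).sum())
    for k, thr in enumerate(thresholds):
        c = confusion_at_threshold(pred, obs, thr)
        acc[k] = accuracy(c)
        acc_pos[k] = c.tp / n_pos if n_pos else np.nan
        acc_neg[k] = c.tn / n_neg if n_neg else np.nan
    gap = np.abs(acc_pos - acc_neg)
    best = int(np.nanargmin(gap)) if np.isfinite(gap).any() else 0
    return AccuracyCurve(
        thresholds=thresholds,
        accuracy=acc,
        per_class_accuracy_pos=acc_pos,
        per_class_accuracy_neg=acc_neg,
        balanced_threshold=float(thresholds[best]),
        balanced_accuracy=float(acc[best]),
    )


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return values
    if transform == "log":
        if np.any(values <= 0):
            raise ValueError("log transform requires strictly positive values")
        return np.log(values)
    raise ValueError(f"unknown transform {transform!r}")


def fit_additive(
    table: pd.DataFrame,
    value_col: str = "value",
    transform: str = "identity",
    aldehyde_col: str = "aldehyde",
    head_col: str = "head",
) -> AdditiveFit:
    """Least-squares fit of f(Y) = A(i) + P(j) on a tidy feature table.

    Handles unbalanced designs and replicates; factor levels with no rows
    are simply absent, and the function warns via ``dropped_levels`` for
    levels the caller declared but that carry no data.  Identifiability:
    the aldehyde effects sum to zero and the heads absorb the intercept.
    """
    df = table.dropna(subset=[value_col])
    y = _apply_transform(df[value_col].to_numpy(dtype=float), transform)
    alds = np.sort(df[aldehyde_col].unique())
    heads = np.sort(df[head_col].unique())
    if len(alds) < 2 or len(heads) < 2:
        raise ValueError("need at least 2 levels per factor")
    a_pos = pd.Series(np.arange(len(alds)), index=alds)
    h_pos = pd.Series(np.arange(len(heads)), index=heads)
    n = len(df)
    # dummies: all head columns + aldehyde columns dropping the first level
    X = np.zeros((n, len(heads) + len(alds) - 1))
    X[np.arange(n), h_pos[df[head_col]].to_numpy()] = 1.0
    ai = a_pos[df[aldehyde_col]].to_numpy()
    nonref = ai > 0
    X[np.nonzero(nonref)[0], len(heads) + ai[nonref] - 1] = 1.0
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    head_eff = coef[: len(heads)]
    ald_eff = np.concatenate([[0.0], coef[len(heads) :]])
    shift = ald_eff.mean()
    alpha = pd.Series(ald_eff - shift, index=alds, name="A")
    beta = pd.Series(head_eff + shift, index=heads, name="P")
    fitted = alpha[df[aldehyde_col]].to_numpy() + beta[df[head_col]].to_numpy()
    return AdditiveFit(
        feature_name=value_col,
        transform=transform,
        alpha=alpha,
        beta=beta,
        residuals=y - fitted,
    )


def cross_validate_additive(
    table: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    value_col: str = "value",
    transform: str = "identity",
    aldehyde_col: str = "aldehyde",
    head_col: str = "head",
) -> np.ndarray:
    """k-fold predictive R² of the additive model over design cells.

    Folds partition the (aldehyde, head) cells, so replicate images of one
    compound never straddle a fold.  Held-out cells whose aldehyde or head
    level is absent from the training fold are not estimable and are
    excluded from that fold's R².  Same seed, same folds.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    df = table.dropna(subset=[value_col]).reset_index(drop=True)
    cells = df[[aldehyde_col, head_col]].drop_duplicates().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    fold_of_cell = np.empty(len(cells), dtype=int)
    fold_of_cell[order] = np.arange(len(cells)) % k
    cell_key = pd.MultiIndex.from_frame(cells)
    fold_map = pd.Series(fold_of_cell, index=cell_key)
    row_fold = fold_map[
        pd.MultiIndex.from_frame(df[[aldehyde_col, head_col]])
    ].to_numpy()

    scores = []
    for fold in range(k):
        train = df[row_fold != fold]
        test = df[row_fold == fold]
        if train.empty or test.empty:
            continue
        fit = fit_additive(
            train,
            value_col=value_col,
            transform=transform,
            aldehyde_col=aldehyde_col,
            head_col=head_col,
        )
        estimable = test[aldehyde_col].isin(fit.alpha.index) & test[
            head_col
        ].isin(fit.beta.index)
        test = test[estimable]
        if test.empty:
            scores.append(np.nan)
            continue
        y = _apply_transform(test[value_col].to_numpy(dtype=float), transform)
        yhat = (
            fit.alpha[test[aldehyde_col]].to_numpy()
            + fit.beta[test[head_col]].to_numpy()
        )
        y_train = _apply_transform(train[value_col].to_numpy(dtype=float), transform)
        ss_tot = np.sum((y - y_train.mean()) ** 2)
        ss_res = np.sum((y - yhat) ** 2)
        scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan)
    return np.asarray(scores)
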