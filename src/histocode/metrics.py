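"""Evaluation statistics for the surrogate-biomarker classifier.

Confusion-matrix metrics with Agresti-Coull binomial intervals, AUC with a
stratified bootstrap interval, Yates-corrected chi-squared association
tests on 2x2 tables, univariable-logistic feature polarity, and spatial
maps of the selected codeword features.  No multiple-testing adjustment is
applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from histocode.codebook import CodebookPairL2, CodeGrid, window_codes

__all__ = [
    "ConfusionMatrix",
    "BinomialCI",
    "FeaturePolarity",
    "confusion",
    "binary_metrics",
    "agresti_coull_ci",
    "auc",
    "bootstrap_auc_ci",
    "chi2_2x2",
    "feature_polarity",
    "spatial_feature_map",
    "threshold_metrics",
]


@dataclass
class ConfusionMatrix:
    """2x2 cross-tabulation; rows = truth, columns = prediction."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass
class BinomialCI:
    point: float
    lower: float
    upper: float
    level: float = 0.95


@dataclass
class FeaturePolarity:
    feature_index: int
    coefficient_sign: int  # +1, -1 or 0
    polarity: str  # "positive" | "negative" | "undetermined"


def confusion(pred_labels: np.ndarray, true_labels: np.ndarray) -> ConfusionMatrix:
    pred = np.asarray(pred_labels).astype(int)
    true = np.asarray(true_labels).astype(int)
    if pred.shape != true.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionMatrix(
        tn=int(np.sum((true == 0) & (pred == 0))),
        fp=int(np.sum((true == 0) & (pred == 1))),
        fn=int(np.sum((true == 1) & (pred == 0))),
        tp=int(np.sum((true == 1) & (pred == 1))),
    )


def binary_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy); an undefined ratio is NaN with a
    warning, never silently zero."""

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
            return float("nan")
        return num / den

    se = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    sp = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    acc = ratio(cm.tp + cm.tn, cm.total, "accuracy")
    return se, sp, acc


def agresti_coull_ci(x: int, n: int, level: float = 0.95) -> BinomialCI:
    """Agresti-Coull adjusted-Wald interval for a binomial proportion.

    With z the normal quantile at (1+level)/2: n~ = n + z^2,
    p~ = (x + z^2/2)/n~, half-width z*sqrt(p~(1-p~)/n~); clipped to [0, 1].
    """
    if n < 1 or x < 0 or x > n:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    z = sps.norm.ppf((1.0 + level) / 2.0)
    n_t = n + z**2
    p_t = (x + z**2 / 2.0) / n_t
    half = z * np.sqrt(p_t * (1.0 - p_t) / n_t)
    return BinomialCI(point=x / n, lower=max(0.0, p_t - half), upper=min(1.0, p_t + half), level=level)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties counted half).

    Scores are oriented so that larger means more positive; an AUC below 0.5
    is reported as-is.
    """
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    reps: int = 2000,
    level: float = 0.95,
    rng_seed: int | None = None,
) -> BinomialCI:
    """Percentile bootstrap interval for the AUC, resampling within each
    class (stratified) so every replicate contains both classes."""
    if reps < 100:
        warnings.warn(f"{reps} bootstrap replicates is too few for a stable interval", stacklevel=2)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    point = auc(scores, labels)
    rng = np.random.default_rng(rng_seed)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    vals = np.empty(reps)
    for r in range(reps):
        take = np.concatenate(
            [rng.choice(idx_pos, size=idx_pos.size), rng.choice(idx_neg, size=idx_neg.size)]
        )
        vals[r] = roc_auc_score(labels[take], scores[take])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return BinomialCI(point=point, lower=float(lo), upper=float(hi), level=level)


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared with Yates continuity correction, 1 d.f."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 count matrix")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins of the 2x2 table must be positive")
    stat, p, _, _ = sps.chi2_contingency(t, correction=True)
    return float(stat), float(p)


def feature_polarity(feature_column: np.ndarray, labels: np.ndarray, feature_index: int = 0) -> FeaturePolarity:
    """Sense of association of one feature with the positive class: the sign
    of the slope of a univariable logistic regression.

    Constant features, non-convergent fits with no usable sign, or a
    negligible slope (|b| < 1e-10) yield "undetermined".  Perfectly separable
    features still have a determinate slope sign; a ridge-stabilised refit is
    used to extract it when the unpenalised fit diverges.
    """
    x = np.asarray(feature_column, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if np.ptp(x) == 0:
        return FeaturePolarity(feature_index, 0, "undetermined")
    slope = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=200)
            if np.isfinite(fit.params[1]):
                slope = float(fit.params[1])
        except Exception:
            slope = None
        if slope is None:
            try:
                fit = sm.Logit(y, sm.add_constant(x)).fit_regularized(alpha=1e-6, disp=0)
                slope = float(fit.params[1])
            except Exception:
                slope = None
    if slope is None or not np.isfinite(slope) or abs(slope) < 1e-10:
        return FeaturePolarity(feature_index, 0, "undetermined")
    sign = 1 if slope > 0 else -1
    return FeaturePolarity(feature_index, sign, "positive" if sign > 0 else "negative")


def threshold_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float, float]:
    """(Se, Sp, Acc) at a given operating point (positive iff score > threshold)."""
    pred = (np.asarray(scores, dtype=float) > threshold).astype(int)
    return binary_metrics(confusion(pred, labels))


def spatial_feature_map(
    grid: CodeGrid,
    pair: CodebookPairL2,
    selected: np.ndarray,
    polarities: dict[int, str],
    window_patches: int = 15,
) -> tuple[np.ndarray, np.ndarray]:
    """Window-resolution maps of where selected codeword features fire.

    Each valid non-overlapping window is marked in the positive map when its
    assigned codeword is a selected feature of positive polarity, in the
    negative map when of negative polarity; invalid (low-contrast/background)
    windows are marked in neither.  ``selected`` holds 0-based feature
    indices; ``polarities`` maps them to "positive"/"negative"/"undetermined".
    """
    selected = np.asarray(selected, dtype=int)
    missing = [int(i) for i in selected if int(i) not in polarities]
    if missing:
        raise ValueError(f"polarity table missing selected features: {missing}")
    codes = window_codes(grid, pair, window_patches=window_patches)
    pos_map = np.zeros(codes.shape, dtype=bool)
    neg_map = np.zeros(codes.shape, dtype=bool)
    for idx in selected:
        pol = polarities[int(idx)]
        where = codes == (int(idx) + 1)  # codes are 1-based
        if pol == "positive":
            pos_map |= where
        elif pol == "negative":
            neg_map |= where
    return pos_map, neg_map
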