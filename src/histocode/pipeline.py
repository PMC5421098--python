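"""Classifier construction and leak-free nested cross-validation.

Per training set the procedure is: (1) order histogram features by
recursive feature elimination using linear-SVM weight magnitudes, (2) for
each candidate subset size tune an RBF-kernel SVM (cost C and kernel width
gamma) by inner stratified cross-validation maximising AUC, (3) keep the
subset size with the best inner AUC and train the final SVM on it.  For an
unbiased performance estimate the whole image-recoding step (L1 codebook,
both L2 codebooks, standardizer) plus (1)-(3) is refitted inside every
training fold of an outer stratified cross-validation, and held-out images
are encoded with the training fold's codebooks only.

Class imbalance is handled by inverse-frequency class weights in every SVM
fit.  All randomness derives from one cohort-level seed: per-image sampling
substreams are keyed by the image identifier, per-fold substreams by the
fold index, so removing a held-out image cannot perturb a fold's fit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from scipy.spatial.distance import cdist

from histocode.codebook import (
    CodebookL1,
    CodebookPairL2,
    encode_image,
    encode_l1,
    fit_l1,
    fit_l2_pair,
    sample_l2_descriptors,
    sample_patch_descriptors,
)
from histocode.config import PipelineConfig
from histocode.extract import ImageFeatures

__all__ = [
    "FeatureRanking",
    "SvmModel",
    "FoldModel",
    "CVReport",
    "rfe_rank",
    "tune_svm",
    "select_subset_size",
    "train_final",
    "predict_margin",
    "fit_fold",
    "encode_cohort",
    "outer_cv",
]


@dataclass
class FeatureRanking:
    """Permutation of 0-based feature indices, most important first."""

    order: np.ndarray
    method_tag: str = "svm-rfe-linear"

    def top(self, f: int) -> np.ndarray:
        return self.order[:f]


@dataclass
class SvmModel:
    """RBF-SVM decision function on a selected feature subset.

    The kernel expansion is stored explicitly so that a model serialized as
    text reproduces margins exactly:
    margin(x) = sum_i a_i exp(-gamma ||sv_i - x_sel||^2) + b.
    """

    selected: np.ndarray  # 0-based indices into the full histogram
    c: float
    gamma: float
    support_vectors: np.ndarray  # (n_sv, f) in selected-feature space
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float
    threshold: float = 0.0

    def decision(self, histograms: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(histograms)[:, self.selected]
        if x.shape[1] != self.support_vectors.shape[1]:
            raise ValueError("histogram dimension does not match the model")
        k = np.exp(-self.gamma * cdist(self.support_vectors, x, metric="sqeuclidean"))
        return self.dual_coef @ k + self.intercept


def predict_margin(model: SvmModel, histogram: np.ndarray) -> tuple[float, int]:
    """Signed decision value and hard label (positive iff margin is strictly
    above the model threshold)."""
    margin = float(model.decision(histogram)[0])
    return margin, int(margin > model.threshold)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y are misaligned")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    return X, y


def rfe_rank(X: np.ndarray, y: np.ndarray, step: int = 5, c: float = 1.0) -> FeatureRanking:
    """Recursive feature elimination with a linear-kernel SVM.

    At each round the ``step`` features with the smallest absolute weight are
    dropped; the elimination order, reversed, is the importance ranking.  The
    linear kernel is used for ranking even though the final classifier is
    RBF — weight magnitudes are only defined for the linear machine.
    """
    X, y = _check_xy(X, y)
    if X.shape[1] < 2:
        raise ValueError("need at least two features to rank")
    if step < 1:
        raise ValueError("step must be >= 1")
    active = np.arange(X.shape[1])
    eliminated: list[int] = []
    while active.size > 1:
        svc = SVC(kernel="linear", C=c, class_weight="balanced")
        svc.fit(X[:, active], y)
        w = np.abs(svc.coef_[0])
        k = min(step, active.size - 1)
        drop = np.argsort(w, kind="stable")[:k]  # least important first
        eliminated.extend(active[drop].tolist())
        active = np.delete(active, drop)
    eliminated.extend(active.tolist())
    return FeatureRanking(order=np.array(eliminated[::-1], dtype=int))


def _inner_splits(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def tune_svm(
    X_sub: np.ndarray,
    y: np.ndarray,
    c_grid: tuple[float, ...],
    gamma_grid: tuple[float, ...],
    inner_folds: int = 5,
    rng_seed: int = 0,
) -> tuple[float, float, float]:
    """Grid-search (C, gamma) maximising mean inner-CV AUC of the decision
    values; ties resolved to the smallest C, then the smallest gamma."""
    X_sub, y = _check_xy(X_sub, y)
    if not len(c_grid) or not len(gamma_grid):
        raise ValueError("hyperparameter grids must be non-empty")
    splits = _inner_splits(y, inner_folds, rng_seed)
    best = (-np.inf, None, None)
    for c in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            aucs = []
            for tr, te in splits:
                if np.unique(y[te]).size < 2:
                    continue
                svc = SVC(kernel="rbf", C=c, gamma=gamma, class_weight="balanced")
                svc.fit(X_sub[tr], y[tr])
                aucs.append(roc_auc_score(y[te], svc.decision_function(X_sub[te])))
            if not aucs:
                raise ValueError("no inner fold contained both classes")
            mean_auc = float(np.mean(aucs))
            if mean_auc > best[0]:
                best = (mean_auc, c, gamma)
    return best[1], best[2], best[0]


def select_subset_size(
    X: np.ndarray,
    y: np.ndarray,
    ranking: FeatureRanking,
    sizes: tuple[int, ...],
    c_grid: tuple[float, ...],
    gamma_grid: tuple[float, ...],
    inner_folds: int = 5,
    rng_seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Tune an SVM on each top-f feature subset; the f with the maximum inner
    AUC wins (ties to the smallest f)."""
    X, y = _check_xy(X, y)
    sizes = tuple(int(f) for f in sizes)
    if any(f > X.shape[1] for f in sizes):
        raise ValueError("subset size exceeds the feature count")
    rows = []
    best_f, best_auc = None, -np.inf
    for f in sizes:
        c, gamma, auc_f = tune_svm(X[:, ranking.top(f)], y, c_grid, gamma_grid, inner_folds, rng_seed)
        rows.append({"f": f, "c": c, "gamma": gamma, "inner_auc": auc_f})
        if auc_f > best_auc:
            best_f, best_auc = f, auc_f
    return best_f, pd.DataFrame(rows)


def train_final(
    X: np.ndarray,
    y: np.ndarray,
    ranking: FeatureRanking,
    f_star: int,
    c: float,
    gamma: float,
    threshold: float = 0.0,
) -> SvmModel:
    """Fit the final RBF SVM on the top-f* features of the whole training set."""
    X, y = _check_xy(X, y)
    selected = ranking.top(f_star)
    svc = SVC(kernel="rbf", C=c, gamma=gamma, class_weight="balanced")
    svc.fit(X[:, selected], y)
    return SvmModel(
        selected=np.asarray(selected, dtype=int),
        c=float(c),
        gamma=float(gamma),
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        threshold=threshold,
    )


# --------------------------------------------------------------------------
# cohort-level fitting


def _image_rng(seed: int, image_id: str, level: int) -> np.random.Generator:
    """Per-image substream, stable across folds and cohort composition."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(image_id.encode()), level]))


def _fold_seed(seed: int, fold: int, stage: int) -> int:
    ss = np.random.SeedSequence([seed, 10_000 + fold, stage])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class FoldModel:
    """Everything fitted on one training set: codebooks plus classifier."""

    codebook_l1: CodebookL1
    codebook_l2: CodebookPairL2
    ranking: FeatureRanking
    f_star: int
    c: float
    gamma: float
    svm: SvmModel
    size_table: pd.DataFrame
    config: PipelineConfig

    def encode(self, feats: ImageFeatures) -> np.ndarray:
        grid = encode_l1(feats, self.codebook_l1)
        return encode_image(grid, self.codebook_l2, window_patches=self.config.window_patches)


def fit_fold(
    train_feats: list[ImageFeatures],
    train_labels: np.ndarray,
    config: PipelineConfig,
    fold_index: int = 0,
) -> FoldModel:
    """Fit codebooks, ranking, tuning and the final SVM on training images only."""
    y = np.asarray(train_labels).astype(int)
    seed = config.seed

    samples = [
        sample_patch_descriptors(f, n=config.l1_samples, rng=_image_rng(seed, f.image_id, 1))
        for f in train_feats
    ]
    pooled = np.vstack([s for s in samples if s.shape[0]])
    cb1 = fit_l1(pooled, k1=config.k1, rng_seed=_fold_seed(seed, fold_index, 1), restarts=config.kmeans_restarts)

    grids = [encode_l1(f, cb1) for f in train_feats]
    l2_by_class: dict[int, list[np.ndarray]] = {0: [], 1: []}
    for feats, grid, label in zip(train_feats, grids, y):
        s = sample_l2_descriptors(
            grid, n=config.l2_samples, rng=_image_rng(seed, feats.image_id, 2), window_patches=config.window_patches
        )
        if s.shape[0]:
            l2_by_class[int(label)].append(s)
    pair = fit_l2_pair(
        np.vstack(l2_by_class[1]),
        np.vstack(l2_by_class[0]),
        k2=config.k2,
        rng_seed=_fold_seed(seed, fold_index, 2),
        restarts=config.kmeans_restarts,
    )

    X = np.vstack([encode_image(g, pair, window_patches=config.window_patches) for g in grids])
    ranking = rfe_rank(X, y, step=config.rfe_step, c=config.rfe_c)
    sizes = tuple(f for f in config.subset_sizes if f <= X.shape[1]) or (X.shape[1],)
    f_star, table = select_subset_size(
        X, y, ranking, sizes, config.c_grid, config.gamma_grid, config.inner_folds,
        rng_seed=_fold_seed(seed, fold_index, 3),
    )
    row = table.loc[table["f"] == f_star].iloc[0]
    svm = train_final(X, y, ranking, int(f_star), float(row["c"]), float(row["gamma"]), threshold=config.threshold)
    return FoldModel(
        codebook_l1=cb1, codebook_l2=pair, ranking=ranking, f_star=int(f_star),
        c=float(row["c"]), gamma=float(row["gamma"]), svm=svm, size_table=table, config=config,
    )


def encode_cohort(model: FoldModel, feats: list[ImageFeatures]) -> np.ndarray:
    return np.vstack([model.encode(f) for f in feats])


def fold_average_auc(predictions: pd.DataFrame) -> float:
    """Out-of-fold AUC averaged over folds.

    Margins from different outer folds are decision values of different SVM
    fits and share no common scale; only within-fold ranking is meaningful,
    so each fold's AUC is computed separately and the mean reported.  Folds
    whose test split contains a single class are skipped.
    """
    from histocode.metrics import auc

    vals = [
        auc(sub["margin"].to_numpy(), sub["true_label"].to_numpy())
        for _, sub in predictions.groupby("fold")
        if sub["true_label"].nunique() > 1
    ]
    if not vals:
        raise ValueError("no fold contained both classes")
    return float(np.mean(vals))


@dataclass
class CVReport:
    """Out-of-fold predictions of the outer cross-validation."""

    predictions: pd.DataFrame  # image_id, fold, margin, predicted_label, true_label
    fold_models: list[FoldModel] = field(default_factory=list)

    @property
    def margins(self) -> np.ndarray:
        return self.predictions["margin"].to_numpy()

    @property
    def true_labels(self) -> np.ndarray:
        return self.predictions["true_label"].to_numpy()

    @property
    def predicted_labels(self) -> np.ndarray:
        return self.predictions["predicted_label"].to_numpy()


def outer_cv(
    cohort_feats: list[ImageFeatures],
    labels: np.ndarray,
    config: PipelineConfig | None = None,
    k: int = 10,
    fold_assignments: np.ndarray | None = None,
    keep_models: bool = False,
) -> CVReport:
    """Outer stratified k-fold cross-validation with full per-fold recoding.

    ``fold_assignments`` (image -> fold) may be supplied to reproduce a given
    split; otherwise folds are stratified on the label using the config seed.
    """
    config = config or PipelineConfig()
    y = np.asarray(labels).astype(int)
    if fold_assignments is None:
        counts = np.bincount(y, minlength=2)
        if counts.min() < k:
            raise ValueError(f"need at least {k} images of each class for {k}-fold stratification")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed % (2**31))
        fold_assignments = np.empty(len(y), dtype=int)
        for fold, (_, te) in enumerate(skf.split(np.zeros_like(y), y)):
            fold_assignments[te] = fold
    fold_assignments = np.asarray(fold_assignments, dtype=int)

    records = []
    models: list[FoldModel] = []
    for fold in np.unique(fold_assignments):
        tr = fold_assignments != fold
        te = ~tr
        model = fit_fold([f for f, m in zip(cohort_feats, tr) if m], y[tr], config, fold_index=int(fold))
        for feats, truth in zip([f for f, m in zip(cohort_feats, te) if m], y[te]):
            hist = model.encode(feats)
            margin, label = predict_margin(model.svm, hist)
            records.append(
                {
                    "image_id": feats.image_id,
                    "fold": int(fold),
                    "margin": margin,
                    "predicted_label": label,
                    "true_label": int(truth),
                    "f_star": model.f_star,
                }
            )
        if keep_models:
            models.append(model)
    return CVReport(predictions=pd.DataFrame(records), fold_models=models)
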