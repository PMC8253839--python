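"""Cross-validated voxel-wise encoding models with permutation inference.

An encoding model maps a category-by-feature matrix (e.g. an 8-dimensional
object-context embedding) onto voxel responses by ordinary least squares,
evaluated out of sample over a fold design in which training and test sets
never share categories. Nuisance regressors absorb unwanted variance during
training only; predictions use the intercept and the model regressors alone.
Inference is permutation-based (category labels of the predicted responses
shuffled within fold), with Benjamini-Hochberg FDR across voxels, bootstrap
standard errors for ROI means, shared-permutation interaction tests, and
preference maps between model pairs.

The cross-validated fit is exposed both as a scikit-learn style estimator
(:class:`VoxelEncoder`, rows = categories) and as the module-level
:func:`fit_predict_cv` operating on voxel-by-category matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import (
    AlignmentError,
    ContractError,
    DomainError,
    RankError,
    SingularDesignError,
)
from .responses import FoldDesign
from .semspace import EmbeddingTable, _signed_pca

__all__ = [
    "FeatureModel",
    "EncodingResult",
    "RoiStat",
    "VoxelEncoder",
    "fit_predict_cv",
    "prediction_accuracy",
    "fold_permutations",
    "permutation_null",
    "fdr_adjust",
    "bootstrap_se",
    "roi_test",
    "interaction_test",
    "preference_map",
    "weights_pca",
]


@dataclass
class FeatureModel:
    """Named category-by-regressor matrix."""

    name: str
    categories: list[str]
    matrix: np.ndarray  # (n_categories, p)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] != len(self.categories):
            raise AlignmentError("feature matrix rows must match categories")

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_embedding(cls, name: str, table: EmbeddingTable,
                       categories: Sequence[str]) -> "FeatureModel":
        return cls(name, list(categories), table.subset(categories).vectors)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "FeatureModel":
        df = pd.read_csv(path, index_col=0)
        return cls(name or str(path), [str(c) for c in df.index], df.to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.categories).to_csv(path)


@dataclass
class EncodingResult:
    """Cross-validated predictions and (optionally) permutation inference."""

    voxels: list[str]
    categories: list[str]
    predicted: np.ndarray  # (n_voxels, n_categories)
    accuracy: np.ndarray  # (n_voxels,)
    weights: np.ndarray  # (n_folds, p, n_voxels), model regressors only
    null_accuracy: np.ndarray | None = None  # (n_perm, n_voxels)
    p_values: np.ndarray | None = None
    q_values: np.ndarray | None = None


@dataclass
class RoiStat:
    roi: str
    voxels: list[str]
    mean_accuracy: float
    bootstrap_se: float | None = None
    p_value: float | None = None


class VoxelEncoder(BaseEstimator):
    """Cross-validated OLS encoder (scikit-learn conventions, rows = categories).

    Parameters
    ----------
    folds : FoldDesign
        Category partition; each fold is held out once.
    nuisance : ndarray of shape (n_categories, q), optional
        Train-only nuisance regressors, aligned to the fold design's
        canonical category order.

    Attributes
    ----------
    predicted_ : ndarray (n_categories, n_targets)
        Held-out predictions, concatenated in canonical category order.
    weights_ : ndarray (n_folds, p, n_targets)
        Per-fold weights of the model regressors (intercept and nuisance
        excluded).
    intercepts_ : ndarray (n_folds, n_targets)
    accuracy_ : ndarray (n_targets,)
        Pearson r between predicted and actual responses per target column.
    """

    def __init__(self, folds: FoldDesign = None, nuisance: np.ndarray | None = None):
        self.folds = folds
        self.nuisance = nuisance

    def fit(self, X: np.ndarray, y: np.ndarray) -> "VoxelEncoder":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        cats = self.folds.categories
        n_cat = len(cats)
        if X.shape[0] != n_cat or Y.shape[0] != n_cat:
            raise AlignmentError("X and y rows must match the fold design categories")
        nuis = None
        if self.nuisance is not None:
            nuis = np.asarray(self.nuisance, dtype=float)
            if nuis.size == 0:
                nuis = None
            elif nuis.shape[0] != n_cat:
                raise AlignmentError("nuisance rows must match categories")
        p = X.shape[1]
        cat_index = {c: i for i, c in enumerate(cats)}
        predicted = np.empty_like(Y)
        weights = np.empty((self.folds.n_folds, p, Y.shape[1]))
        intercepts = np.empty((self.folds.n_folds, Y.shape[1]))
        for f, fold_cats in enumerate(self.folds.folds):
            test = np.array([cat_index[c] for c in fold_cats])
            train = np.setdiff1d(np.arange(n_cat), test)
            cols = [np.ones((len(train), 1)), X[train]]
            if nuis is not None:
                cols.append(nuis[train])
            design = np.hstack(cols)
            if len(train) <= design.shape[1] - 1 or (
                np.linalg.matrix_rank(design) < design.shape[1]
            ):
                raise SingularDesignError(
                    f"rank-deficient training design on fold {f} "
                    f"({len(train)} categories, {design.shape[1]} columns)"
                )
            beta, *_ = np.linalg.lstsq(design, Y[train], rcond=None)
            intercepts[f] = beta[0]
            weights[f] = beta[1 : 1 + p]
            predicted[test] = beta[0] + X[test] @ beta[1 : 1 + p]
        self.predicted_ = predicted
        self.weights_ = weights
        self.intercepts_ = intercepts
        self.accuracy_ = _columnwise_pearson(predicted, Y)
        return self

    def predict(self, X: np.ndarray = None) -> np.ndarray:
        """Return the cross-validated held-out predictions."""
        return self.predicted_


def _columnwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of A and B; NaN where constant."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na = np.linalg.norm(Ac, axis=0)
    nb = np.linalg.norm(Bc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac * Bc).sum(axis=0) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return r


def fit_predict_cv(
    model: FeatureModel,
    nuisance: FeatureModel | None,
    Y: np.ndarray,
    folds: FoldDesign,
    voxels: Sequence[str] | None = None,
) -> EncodingResult:
    """Cross-validated OLS encoding of ``Y`` (voxel x category) by ``model``.

    Nuisance regressors, if given, enter the training design only;
    held-out predictions use intercept + model columns.
    """
    cats = folds.categories
    if model.categories != cats:
        raise AlignmentError(
            f"model '{model.name}' categories do not match the fold design"
        )
    if nuisance is not None and nuisance.categories != cats:
        raise AlignmentError("nuisance categories do not match the fold design")
    Y = np.asarray(Y, dtype=float)
    if Y.shape[1] != len(cats):
        raise AlignmentError("Y columns must match categories")
    vox = [f"v{i}" for i in range(Y.shape[0])] if voxels is None else list(voxels)
    enc = VoxelEncoder(
        folds=folds, nuisance=None if nuisance is None else nuisance.matrix
    ).fit(model.matrix, Y.T)
    return EncodingResult(
        voxels=vox,
        categories=cats,
        predicted=enc.predicted_.T,
        accuracy=enc.accuracy_,
        weights=enc.weights_,
    )


def prediction_accuracy(predicted: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Per-voxel Pearson r between predicted and actual category responses."""
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    actual = np.atleast_2d(np.asarray(actual, dtype=float))
    if predicted.shape != actual.shape:
        raise AlignmentError("predicted and actual must have the same shape")
    return _columnwise_pearson(predicted.T, actual.T)


def fold_permutations(folds: FoldDesign, n_perm: int, seed: int) -> np.ndarray:
    """Seeded stream of within-fold category permutations.

    Returns an (n_perm, n_categories) index array: each row permutes the
    canonical category order independently within every fold. Reusing one
    stream across two models is what makes their difference tests valid.
    """
    rng = np.random.default_rng(seed)
    cats = folds.categories
    cat_index = {c: i for i, c in enumerate(cats)}
    blocks = [np.array([cat_index[c] for c in f]) for f in folds.folds]
    perms = np.empty((n_perm, len(cats)), dtype=int)
    for k in range(n_perm):
        row = np.arange(len(cats))
        for blk in blocks:
            row[blk] = blk[rng.permutation(len(blk))]
        perms[k] = row
    return perms


def permutation_null(
    result: EncodingResult,
    actual: np.ndarray,
    folds: FoldDesign,
    n_perm: int = 5000,
    seed: int = 0,
    permutations: np.ndarray | None = None,
) -> EncodingResult:
    """Permutation null for prediction accuracy, with one-sided p-values.

    The category labels of the *predicted* responses are permuted within
    each fold; null accuracy is the correlation of the permuted predictions
    with the actual responses. ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    actual = np.asarray(actual, dtype=float)
    if permutations is None:
        permutations = fold_permutations(folds, n_perm, seed)
    n_perm = permutations.shape[0]
    null = np.empty((n_perm, len(result.voxels)))
    A = actual.T - actual.T.mean(axis=0)
    nb = np.linalg.norm(A, axis=0)
    for k in range(n_perm):
        P = result.predicted[:, permutations[k]].T
        P = P - P.mean(axis=0)
        na = np.linalg.norm(P, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            null[k] = (P * A).sum(axis=0) / (na * nb)
    obs = result.accuracy
    exceed = (null >= obs[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    result.null_accuracy = null
    result.p_values = p
    result.q_values = fdr_adjust(p)
    return result


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_se(
    predicted: np.ndarray,
    actual: np.ndarray,
    folds: FoldDesign,
    roi: Sequence[int],
    n_boot: int = 5000,
    seed: int = 0,
) -> float:
    """Bootstrap SE of an ROI's mean accuracy, resampling within folds.

    Each replicate resamples category indices with replacement independently
    within every fold (paired predicted/actual), recomputes the voxel
    correlations over ROI voxels and takes the ROI mean; the returned SE is
    the standard deviation over replicates. Replicates that produce a
    constant vector are redrawn (counted and warned).
    """
    predicted = np.asarray(predicted, dtype=float)[list(roi), :]
    actual = np.asarray(actual, dtype=float)[list(roi), :]
    cats = folds.categories
    cat_index = {c: i for i, c in enumerate(cats)}
    blocks = [np.array([cat_index[c] for c in f]) for f in folds.folds]
    rng = np.random.default_rng(seed)
    means = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = np.concatenate(
                [blk[rng.integers(0, len(blk), size=len(blk))] for blk in blocks]
            )
            r = _columnwise_pearson(predicted[:, idx].T, actual[:, idx].T)
            if not np.isnan(r).any():
                break
            n_redrawn += 1
        means[b] = r.mean()
    if n_redrawn:
        warnings.warn(f"{n_redrawn} bootstrap replicates redrawn (constant vector)",
                      stacklevel=2)
    return float(means.std(ddof=0))


def _flat_mean(per_subject: Sequence[np.ndarray], roi: Sequence[int]) -> float:
    """Mean over voxels x subjects of ROI-restricted per-voxel values."""
    return float(np.mean([np.asarray(a)[list(roi)] for a in per_subject]))


def roi_test(
    accuracy_per_subject: Sequence[np.ndarray],
    null_per_subject: Sequence[np.ndarray],
    roi: Sequence[int],
    roi_name: str = "roi",
    voxel_ids: Sequence[str] | None = None,
) -> RoiStat:
    """Permutation test of an ROI's mean accuracy across voxels and subjects.

    The observed statistic is the flat average of per-voxel accuracy over
    (ROI voxels x subjects); the identical averaging is applied to every
    permutation replicate of the null.
    """
    roi = list(roi)
    if len(roi) == 0:
        raise DomainError("empty ROI")
    n_perm = {np.asarray(n).shape[0] for n in null_per_subject}
    if len(n_perm) != 1:
        raise ContractError("null accuracy arrays must share one permutation stream")
    n_perm = n_perm.pop()
    observed = _flat_mean(accuracy_per_subject, roi)
    null_means = np.mean(
        [np.asarray(n)[:, roi].mean(axis=1) for n in null_per_subject], axis=0
    )
    p = float((1.0 + (null_means >= observed).sum()) / (1.0 + n_perm))
    ids = [str(i) for i in roi] if voxel_ids is None else [voxel_ids[i] for i in roi]
    return RoiStat(roi_name, ids, observed, p_value=p)


def interaction_test(
    acc_a: Sequence[np.ndarray],
    acc_b: Sequence[np.ndarray],
    null_a: Sequence[np.ndarray],
    null_b: Sequence[np.ndarray],
    roi_1: Sequence[int],
    roi_2: Sequence[int],
) -> tuple[float, float]:
    """Permutation interaction: does the A-B advantage differ between ROIs?

    statistic = mean_roi1(A - B) - mean_roi2(A - B), averaged over voxels and
    subjects; the same statistic is computed on each joint permutation
    replicate. A and B nulls must come from one shared permutation stream.
    """
    shapes = {np.asarray(n).shape for n in null_a} | {np.asarray(n).shape for n in null_b}
    if len(shapes) != 1:
        raise ContractError("A and B null arrays must share one permutation stream")
    n_perm = shapes.pop()[0]
    diff = [np.asarray(a) - np.asarray(b) for a, b in zip(acc_a, acc_b)]
    observed = _flat_mean(diff, roi_1) - _flat_mean(diff, roi_2)
    null_diff = [np.asarray(na) - np.asarray(nb) for na, nb in zip(null_a, null_b)]
    null_stat = (
        np.mean([d[:, list(roi_1)].mean(axis=1) for d in null_diff], axis=0)
        - np.mean([d[:, list(roi_2)].mean(axis=1) for d in null_diff], axis=0)
    )
    p = float((1.0 + (null_stat >= observed).sum()) / (1.0 + n_perm))
    return observed, p


@dataclass
class PreferenceMap:
    difference: np.ndarray  # zero-floored acc_A - acc_B per voxel
    p_a_over_b: np.ndarray
    p_b_over_a: np.ndarray
    q_a_over_b: np.ndarray
    q_b_over_a: np.ndarray
    preference: np.ndarray = field(init=False)  # +1 A, -1 B, 0 neither

    def __post_init__(self) -> None:
        self.preference = np.zeros(self.difference.shape, dtype=int)
        self.preference[self.q_a_over_b < 0.05] = 1
        self.preference[self.q_b_over_a < 0.05] = -1


def preference_map(
    acc_a: np.ndarray,
    acc_b: np.ndarray,
    null_a: np.ndarray,
    null_b: np.ndarray,
    fdr_alpha: float = 0.05,
) -> PreferenceMap:
    """Voxel-wise model preference with zero-floored accuracy differences.

    Negative accuracies are floored at zero before differencing (both for
    the observed values and every permutation replicate) so that an apparent
    preference cannot be driven by the comparison model's negative
    correlation. Two one-sided permutation tests (A>B and B>A) are each
    FDR-corrected; a voxel is assigned to whichever direction is significant.
    """
    if np.asarray(null_a).shape != np.asarray(null_b).shape:
        raise ContractError("A and B nulls must share one permutation stream")
    diff = np.maximum(acc_a, 0.0) - np.maximum(acc_b, 0.0)
    null_diff = np.maximum(null_a, 0.0) - np.maximum(null_b, 0.0)
    n_perm = null_diff.shape[0]
    p_ab = (1.0 + (null_diff >= diff[None, :]).sum(axis=0)) / (1.0 + n_perm)
    p_ba = (1.0 + (-null_diff >= -diff[None, :]).sum(axis=0)) / (1.0 + n_perm)
    out = PreferenceMap(diff, p_ab, p_ba, fdr_adjust(p_ab), fdr_adjust(p_ba))
    if fdr_alpha != 0.05:
        out.preference = np.zeros(diff.shape, dtype=int)
        out.preference[out.q_a_over_b < fdr_alpha] = 1
        out.preference[out.q_b_over_a < fdr_alpha] = -1
    return out


def weights_pca(
    weights: np.ndarray,
    significant: Sequence[int],
    model: FeatureModel,
    n_components: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of encoding weights across voxels, projected back onto categories.

    ``weights`` is (n_voxels, p): subject- and fold-averaged model-regressor
    weights (intercept and nuisance excluded). PCA treats voxels as
    observations; the loadings of the first ``n_components`` are applied to
    the model's category-by-regressor matrix to yield per-category PC scores.

    Returns (loadings (p, k), category_scores (n_categories, k),
    explained_variance_ratio).
    """
    sig = list(significant)
    if len(sig) < n_components + 1:
        raise RankError(
            f"need at least {n_components + 1} significant voxels, got {len(sig)}"
        )
    W = np.asarray(weights, dtype=float)[sig, :]
    if W.shape[1] != model.p:
        raise AlignmentError("weight columns must match the model's regressors")
    _, loadings, evr = _signed_pca(W, n_components)
    category_scores = model.matrix @ loadings
    return loadings, category_scores, evr
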