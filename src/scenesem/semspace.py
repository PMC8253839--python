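"""Embedding tables, representational dissimilarity matrices and RSA.

This module holds the shared currency of every model comparison in the
package: labelled embedding tables (word2vec text format), Pearson-distance
RDMs, Spearman RSA correlations between RDMs, and the ``r_max`` criterion
(the maximum RSA correlation over a set of target x nuisance comparisons)
used for stimulus-set optimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .errors import (
    AlignmentError,
    FormatError,
    RankError,
    UndefinedDistanceError,
    UnknownLabelError,
)

__all__ = [
    "EmbeddingTable",
    "RDM",
    "read_embedding_text",
    "write_embedding_text",
    "average_names",
    "pca_reduce",
    "pearson_distance",
    "make_rdm",
    "rsa_correlation",
    "r_max",
]


@dataclass
class EmbeddingTable:
    """An ordered set of labels with one real vector per label."""

    labels: list[str]
    vectors: np.ndarray  # (n_labels, dim)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.labels):
            raise FormatError("vectors must be (n_labels, dim)")
        if len(set(self.labels)) != len(self.labels):
            raise FormatError("duplicate labels in embedding table")
        if not np.all(np.isfinite(self.vectors)):
            raise FormatError("non-finite entries in embedding table")
        self._index = {lbl: i for i, lbl in enumerate(self.labels)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def vector(self, label: str) -> np.ndarray:
        try:
            return self.vectors[self._index[label]]
        except KeyError:
            raise UnknownLabelError(f"label not in table: {label!r}") from None

    def subset(self, labels: Sequence[str]) -> "EmbeddingTable":
        missing = [l for l in labels if l not in self._index]
        if missing:
            raise UnknownLabelError(f"labels not in table: {missing}")
        idx = [self._index[l] for l in labels]
        return EmbeddingTable(list(labels), self.vectors[idx].copy())


def read_embedding_text(
    path: str | Path, vocabulary_filter: set[str] | None = None
) -> EmbeddingTable:
    """Read a word2vec-style text file: header ``n dim``, then label + values.

    Labels are stored with spaces replaced by underscores on disk; the
    underscores are converted back to spaces on read.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}:1: expected header '<n_labels> <dim>'")
        try:
            n, dim = int(header[0]), int(header[1])
        except ValueError:
            raise FormatError(f"{path}:1: non-integer header") from None
        labels, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            label = parts[0].replace("_", " ")
            values = parts[1:]
            if len(values) != dim:
                raise FormatError(
                    f"{path}:{lineno}: expected {dim} values, got {len(values)}"
                )
            if vocabulary_filter is not None and label not in vocabulary_filter:
                continue
            labels.append(label)
            try:
                rows.append([float(v) for v in values])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from None
    if vocabulary_filter is None and len(labels) != n:
        raise FormatError(f"{path}: header declares {n} rows, found {len(labels)}")
    return EmbeddingTable(labels, np.array(rows, dtype=float))


def write_embedding_text(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dim}\n")
        for label, vec in zip(table.labels, table.vectors):
            fh.write(
                label.replace(" ", "_")
                + " "
                + " ".join(repr(float(v)) for v in vec)
                + "\n"
            )


def average_names(table: EmbeddingTable, names: Mapping[str, Sequence[str]]) -> EmbeddingTable:
    """One vector per category: the unweighted mean over its resolvable names.

    Emulates deriving category vectors from a large word-embedding table in
    which each category has a list of associated names (synonyms, plurals).
    Names absent from the table are skipped; a category whose names all fail
    to resolve is an error.
    """
    labels, rows, unresolved = [], [], []
    for category, name_list in names.items():
        present = [nm for nm in name_list if nm in table]
        if not present:
            unresolved.append(category)
            continue
        labels.append(category)
        rows.append(np.mean([table.vector(nm) for nm in present], axis=0))
    if unresolved:
        raise UnknownLabelError(f"categories with no resolvable name: {unresolved}")
    return EmbeddingTable(labels, np.array(rows))


def _signed_pca(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-centered PCA with a deterministic sign convention.

    Each component is flipped so that its largest-magnitude loading is
    positive. Returns (scores, loadings, explained_variance_ratio) with
    loadings of shape (n_features, k).
    """
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if k > rank:
        raise RankError(f"requested {k} components but data rank is {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # (n_features, k)
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return scores, loadings, pca.explained_variance_ratio_


def pca_reduce(table: EmbeddingTable, k: int) -> EmbeddingTable:
    """Reduce an embedding table to its top-k principal-component scores."""
    if k > min(len(table) - 1, table.dim):
        raise RankError(
            f"k={k} exceeds min(n_labels-1, dim) = {min(len(table) - 1, table.dim)}"
        )
    scores, _, _ = _signed_pca(table.vectors, k)
    return EmbeddingTable(list(table.labels), scores)


def pearson_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson distance: one minus the Pearson correlation; in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 3:
        raise UndefinedDistanceError("vectors must be 1-D, equal length >= 3")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise UndefinedDistanceError("Pearson distance undefined for constant vector")
    r = np.corrcoef(u, v)[0, 1]
    return float(1.0 - r)


@dataclass
class RDM:
    """Category-by-category Pearson-distance matrix; symmetric, zero diagonal."""

    categories: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.categories = list(self.categories)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.categories)
        if self.values.shape != (n, n):
            raise FormatError("RDM must be square over its categories")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite RDM entries")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise FormatError("RDM must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise FormatError("RDM diagonal must be zero")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.categories), k=1)
        return self.values[iu]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.categories, columns=self.categories).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RDM":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy())


def make_rdm(
    source: EmbeddingTable | np.ndarray,
    categories: Sequence[str],
) -> RDM:
    """Pairwise Pearson-distance RDM over categories (rows of the feature matrix)."""
    if isinstance(source, EmbeddingTable):
        X = source.subset(categories).vectors
    else:
        X = np.asarray(source, dtype=float)
        if X.shape[0] != len(categories):
            raise AlignmentError("feature matrix rows must match categories")
    if X.shape[1] < 3:
        raise UndefinedDistanceError("need vectors of length >= 3 for Pearson distance")
    ptp = np.ptp(X, axis=1)
    if np.any(ptp == 0):
        bad = [categories[i] for i in np.flatnonzero(ptp == 0)]
        raise UndefinedDistanceError(f"constant representational vector for: {bad}")
    values = 1.0 - np.corrcoef(X)
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return RDM(list(categories), values)


def rsa_correlation(a: RDM, b: RDM) -> float:
    """Spearman correlation between the strictly-upper triangles of two RDMs."""
    if a.categories != b.categories:
        raise AlignmentError("RDMs must share categories in the same order")
    if len(a.categories) < 4:
        raise AlignmentError("RSA requires at least 4 categories")
    rho = stats.spearmanr(a.upper_triangle(), b.upper_triangle()).statistic
    return float(rho)


def r_max(target_rdms: Iterable[RDM], nuisance_rdms: Iterable[RDM]) -> float:
    """Maximum (signed) RSA correlation over all target x nuisance pairs."""
    targets = list(target_rdms)
    nuisances = list(nuisance_rdms)
    if not targets or not nuisances:
        raise AlignmentError("both RDM lists must be non-empty")
    return max(rsa_correlation(t, nuis) for t in targets for nuis in nuisances)
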