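"""Object-context embeddings from scene annotations (object2vec).

Labels are treated like word tokens whose context window is *all other
objects in the same scene*, with equal weight — the bag-of-words analogue of
CBOW for image annotations. Training optimizes the CBOW objective with
negative sampling by stochastic gradient descent: predict each target label
from the mean of its context vectors, discriminating it from noise labels
drawn from the unigram distribution raised to a smoothing power.

The estimator follows scikit-learn conventions (`fit`, `get_params`,
fitted attributes with trailing underscores); module-level functions wrap it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator

from .corpus import AnnotationCorpus
from .errors import DomainError, NoTrainableDataError, UnknownLabelError
from .semspace import RDM, EmbeddingTable, _signed_pca, make_rdm, rsa_correlation

__all__ = [
    "TrainConfig",
    "Object2Vec",
    "training_pairs",
    "train_cbow",
    "train_ensemble",
    "average_rdm",
    "dimensionality_rsa",
    "aggregate_pca",
]

#: Exponent applied to unigram counts for the negative-sampling noise
#: distribution; the standard word2vec smoothing power.
NOISE_POWER = 0.75

#: Learning rate decays linearly to this fraction of its initial value.
LR_FLOOR_FRACTION = 1e-4


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of a single CBOW training run.

    Defaults are the reference configuration for annotation corpora: a
    10-dimensional embedding trained for 1000 epochs with 20 negative
    samples per positive.
    """

    dim: int = 10
    epochs: int = 1000
    negatives: int = 20
    learning_rate: float = 0.05
    min_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.epochs < 1 or self.negatives < 1:
            raise DomainError("dim, epochs and negatives must all be >= 1")
        if self.learning_rate <= 0:
            raise DomainError("learning_rate must be positive")


def training_pairs(scene: tuple[str, ...]) -> list[tuple[str, frozenset[str]]]:
    """Enumerate (target, context-set) pairs for one scene.

    Each label in the scene serves once as the target, with all other labels
    of the scene as its equally weighted context. Scenes with fewer than two
    labels yield no pairs.
    """
    if len(scene) < 2:
        return []
    full = frozenset(scene)
    return [(label, full - {label}) for label in scene]


@njit(cache=False)
def _sgd_train(tokens, offsets, w_in, w_out, noise_cdf, epochs, negatives,
               lr0, lr_floor, seed, total_pairs):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_scenes = offsets.shape[0] - 1
    dim = w_in.shape[1]
    order = np.arange(n_scenes)
    h = np.empty(dim)
    grad = np.empty(dim)
    pair_count = 0
    for _epoch in range(epochs):
        # Fisher-Yates shuffle of scene order, driven by the seeded stream
        for i in range(n_scenes - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        for si in range(n_scenes):
            s = order[si]
            start = offsets[s]
            end = offsets[s + 1]
            size = end - start
            if size < 2:
                continue
            for t_pos in range(start, end):
                target = tokens[t_pos]
                lr = lr0 * (1.0 - pair_count / total_pairs)
                if lr < lr_floor:
                    lr = lr_floor
                pair_count += 1
                for d in range(dim):
                    h[d] = 0.0
                for c_pos in range(start, end):
                    if c_pos == t_pos:
                        continue
                    c = tokens[c_pos]
                    for d in range(dim):
                        h[d] += w_in[c, d]
                inv = 1.0 / (size - 1)
                for d in range(dim):
                    h[d] *= inv
                    grad[d] = 0.0
                for k in range(negatives + 1):
                    if k == 0:
                        j = target
                        label = 1.0
                    else:
                        j = np.searchsorted(noise_cdf, np.random.random())
                        while j == target:
                            j = np.searchsorted(noise_cdf, np.random.random())
                        label = 0.0
                    dot = 0.0
                    for d in range(dim):
                        dot += h[d] * w_out[j, d]
                    if dot > 8.0:
                        score = 1.0
                    elif dot < -8.0:
                        score = 0.0
                    else:
                        score = 1.0 / (1.0 + math.exp(-dot))
                    g = lr * (label - score)
                    for d in range(dim):
                        grad[d] += g * w_out[j, d]
                        w_out[j, d] += g * h[d]
                for d in range(dim):
                    grad[d] *= inv
                for c_pos in range(start, end):
                    if c_pos == t_pos:
                        continue
                    c = tokens[c_pos]
                    for d in range(dim):
                        w_in[c, d] += grad[d]


class Object2Vec(BaseEstimator):
    """CBOW-with-negative-sampling embedding learner for annotation corpora.

    Parameters mirror :class:`TrainConfig`. After :meth:`fit`, the learned
    input-side (context-average) vectors are available as ``embedding_``.

    Attributes
    ----------
    labels_ : list of str
        Trained vocabulary, ordered by descending scene count then label.
    embedding_ : EmbeddingTable
        Input-side embedding vectors, one row per trained label.
    """

    def __init__(self, dim=10, epochs=1000, negatives=20, learning_rate=0.05,
                 min_count=1, seed=0):
        self.dim = dim
        self.epochs = epochs
        self.negatives = negatives
        self.learning_rate = learning_rate
        self.min_count = min_count
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(self.dim, self.epochs, self.negatives,
                           self.learning_rate, self.min_count, self.seed)

    def fit(self, X: AnnotationCorpus, y=None) -> "Object2Vec":
        """Train on an :class:`AnnotationCorpus`; returns self."""
        cfg = self._config()
        vocab = [lbl for lbl, cnt in X.vocabulary.items() if cnt >= cfg.min_count]
        # deterministic order: frequency-descending, label as tie-break
        vocab.sort(key=lambda lbl: (-X.vocabulary[lbl], lbl))
        index = {lbl: i for i, lbl in enumerate(vocab)}

        token_runs, offsets, total = [], [0], 0
        n_pairs = 0
        for scene in X.scenes:
            ids = [index[lbl] for lbl in scene if lbl in index]
            token_runs.extend(ids)
            total += len(ids)
            offsets.append(total)
            if len(ids) >= 2:
                n_pairs += len(ids)
        if not vocab or n_pairs == 0:
            raise NoTrainableDataError(
                "no scene with >= 2 in-vocabulary labels after min_count filtering"
            )

        counts = np.array([X.vocabulary[lbl] for lbl in vocab], dtype=float)
        noise = counts ** NOISE_POWER
        noise_cdf = np.cumsum(noise / noise.sum())
        noise_cdf[-1] = 1.0

        rng = np.random.RandomState(cfg.seed)
        w_in = (rng.rand(len(vocab), cfg.dim) - 0.5) / cfg.dim
        w_out = np.zeros((len(vocab), cfg.dim))

        _sgd_train(
            np.asarray(token_runs, dtype=np.int64),
            np.asarray(offsets, dtype=np.int64),
            w_in, w_out, noise_cdf,
            cfg.epochs, cfg.negatives,
            cfg.learning_rate, cfg.learning_rate * LR_FLOOR_FRACTION,
            cfg.seed, cfg.epochs * n_pairs,
        )
        self.labels_ = vocab
        self.embedding_ = EmbeddingTable(vocab, w_in)
        return self

    def transform(self, labels) -> np.ndarray:
        """Return the learned vectors for the given labels."""
        return self.embedding_.subset(list(labels)).vectors


def train_cbow(corpus: AnnotationCorpus, cfg: TrainConfig) -> EmbeddingTable:
    """Train a single CBOW model; deterministic for a fixed config and corpus."""
    est = Object2Vec(**{f: getattr(cfg, f) for f in
                        ("dim", "epochs", "negatives", "learning_rate",
                         "min_count", "seed")})
    return est.fit(corpus).embedding_


def train_ensemble(corpus: AnnotationCorpus, cfg: TrainConfig,
                   n_inits: int) -> list[EmbeddingTable]:
    """Train ``n_inits`` models with consecutive seeds ``seed, seed+1, ...``."""
    if n_inits < 1:
        raise DomainError("n_inits must be >= 1")
    return [train_cbow(corpus, replace(cfg, seed=cfg.seed + i)) for i in range(n_inits)]


def average_rdm(tables: list[EmbeddingTable], labels_of_interest) -> RDM:
    """Element-wise mean of the Pearson-distance RDMs of several tables."""
    labels = list(labels_of_interest)
    rdms = [make_rdm(t, labels) for t in tables]
    return RDM(labels, np.mean([r.values for r in rdms], axis=0))


def dimensionality_rsa(corpus: AnnotationCorpus, dims: list[int], n_inits: int,
                       labels_of_interest, cfg: TrainConfig | None = None) -> np.ndarray:
    """Compare embedding dimensionalities through their ensemble-averaged RDMs.

    For each dimensionality, an ensemble of ``n_inits`` models is trained
    (seeds ``cfg.seed .. cfg.seed+n_inits-1``), their RDMs over the labels of
    interest averaged, and the Spearman RSA correlation computed between the
    averaged RDMs of every pair of dimensionalities.
    """
    cfg = cfg or TrainConfig()
    labels = list(labels_of_interest)
    missing = [l for l in labels if l not in corpus.vocabulary]
    if missing:
        raise UnknownLabelError(f"labels of interest absent from corpus: {missing}")
    avg = [average_rdm(train_ensemble(corpus, replace(cfg, dim=d), n_inits), labels)
           for d in dims]
    n = len(dims)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = rsa_correlation(avg[i], avg[j])
    return out


def aggregate_pca(tables: list[EmbeddingTable], n_components: int,
                  labels_of_interest) -> EmbeddingTable:
    """Aggregate an ensemble by PCA of the concatenated embedding columns.

    Rows are the labels of interest; columns are the concatenation of every
    table's dimensions. Columns are mean-centered and the top
    ``n_components`` PC scores form the final embedding, with each
    component's sign fixed so its largest-magnitude loading is positive.
    """
    labels = list(labels_of_interest)
    X = np.hstack([t.subset(labels).vectors for t in tables])
    scores, _, _ = _signed_pca(X, n_components)
    return EmbeddingTable(labels, scores)
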