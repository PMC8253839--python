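"""Synthetic-data generators with known ground truth.

Every stage of the pipeline can be exercised without any external download:
scene corpora are generated from latent context categories with
category-specific object distributions (emulating densely annotated scene
datasets, scaled to desk size), voxel responses are linear in a known
embedding with additive Gaussian noise at the beta level and a run/fold
structure, and rating panels contain honest raters plus injected
random-rating outliers. Each generator consumes one explicit seed and
returns its ground truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import AnnotationCorpus
from .errors import SpecError, UnknownLabelError
from .ratings import RatingPanel
from .responses import FoldDesign, ResponseData
from .semspace import EmbeddingTable

__all__ = [
    "CorpusSpec",
    "NuisanceSpec",
    "ResponseSpec",
    "generate_corpus",
    "generate_responses",
    "generate_rating_panel",
    "default_fold_design",
]


def default_fold_design(n_folds: int = 9, per_fold: int = 9) -> FoldDesign:
    """The reference design: 9 folds of 9 categories each (81 categories)."""
    cats = [f"cat{i:03d}" for i in range(n_folds * per_fold)]
    return FoldDesign([cats[i * per_fold:(i + 1) * per_fold] for i in range(n_folds)])


@dataclass(frozen=True)
class CorpusSpec:
    """Generator settings for a context-structured annotation corpus.

    Defaults are the reference desk-scale conditions: 2000 scenes over an
    80-label vocabulary split into 4 latent contexts, scenes of about 6
    objects, and purity 0.9 (each object label drawn from the scene's own
    context with probability 0.9).
    """

    n_scenes: int = 2000
    vocab_size: int = 80
    n_latent_contexts: int = 4
    concentration: float = 1.0
    mean_objects: float = 6.0
    dispersion: float = 4.0
    min_objects: int = 2
    purity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise SpecError("purity must lie in [0, 1]")
        if self.n_latent_contexts < 1:
            raise SpecError("need at least one latent context")
        if self.vocab_size < self.n_latent_contexts:
            raise SpecError("vocabulary smaller than the number of contexts")
        per_context = self.vocab_size // self.n_latent_contexts
        if self.mean_objects > per_context:
            raise SpecError(
                f"mean_objects={self.mean_objects} exceeds per-context "
                f"vocabulary size {per_context}"
            )


def generate_corpus(
    spec: CorpusSpec,
) -> tuple[AnnotationCorpus, list[int], dict[str, int]]:
    """Generate a corpus plus scene->context and label->home-context maps.

    Each scene draws a latent context uniformly, a scene size from a shifted
    negative binomial, then object labels without replacement from the
    context's Dirichlet-weighted label distribution; with probability
    ``1 - purity`` an individual label is drawn from a random other context
    instead.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_latent_contexts
    labels = [f"obj{i:03d}" for i in range(spec.vocab_size)]
    bounds = np.linspace(0, spec.vocab_size, K + 1).astype(int)
    context_labels = [labels[bounds[k]:bounds[k + 1]] for k in range(K)]
    label_context = {l: k for k in range(K) for l in context_labels[k]}
    context_probs = [
        rng.dirichlet(np.full(len(context_labels[k]), spec.concentration))
        for k in range(K)
    ]

    # shifted negative binomial: size = min_objects + NB(r, p), mean as given
    extra_mean = max(spec.mean_objects - spec.min_objects, 0.0)
    r = spec.dispersion
    p_nb = r / (r + extra_mean) if extra_mean > 0 else 1.0

    scenes: list[list[str]] = []
    scene_contexts: list[int] = []
    max_size = min(len(cl) for cl in context_labels)
    for _ in range(spec.n_scenes):
        k = int(rng.integers(0, K))
        size = spec.min_objects + (rng.negative_binomial(r, p_nb) if extra_mean > 0 else 0)
        size = int(min(size, max_size))
        scene: list[str] = []
        taken: set[str] = set()
        # sample without replacement: drawn labels are removed from their
        # context's distribution and the remainder renormalized, so each
        # draw comes from the scene's own context with probability `purity`
        while len(scene) < size:
            if K > 1 and rng.random() > spec.purity:
                other = int(rng.integers(0, K - 1))
                src = other if other < k else other + 1
            else:
                src = k
            avail = [i for i, l in enumerate(context_labels[src]) if l not in taken]
            if not avail:
                continue
            p = context_probs[src][avail]
            lbl = context_labels[src][rng.choice(avail, p=p / p.sum())]
            scene.append(str(lbl))
            taken.add(lbl)
        scenes.append(scene)
        scene_contexts.append(k)
    return AnnotationCorpus(scenes), scene_contexts, label_context


@dataclass(frozen=True)
class NuisanceSpec:
    """Nuisance feature layer: dimensionality, correlation with the model
    features, and the scale of its (optional) contribution to responses."""

    p: int = 20
    correlation: float = 0.0
    weight_scale: float = 0.0


@dataclass(frozen=True)
class ResponseSpec:
    """Generator settings for voxel responses linear in a known embedding."""

    n_voxels: int = 200
    weight_scale: float = 1.0
    intercept_scale: float = 0.5
    noise_sd: float = 0.5
    n_runs_per_fold: int = 4
    nuisance: NuisanceSpec | None = None
    seed: int = 0


def generate_responses(
    spec: ResponseSpec,
    embedding: EmbeddingTable,
    fold_design: FoldDesign,
) -> tuple[ResponseData, dict]:
    """Voxel betas = intercept + embedding @ weights (+ nuisance) + noise.

    Noise is i.i.d. Gaussian per (voxel, category, run) observation at the
    beta level. Returns the data plus ground truth (weights, intercepts,
    noiseless responses, nuisance features/weights).
    """
    cats = fold_design.categories
    missing = [c for c in cats if c not in embedding]
    if missing:
        raise UnknownLabelError(f"embedding does not cover categories: {missing}")
    rng = np.random.default_rng(spec.seed)
    E = embedding.subset(cats).vectors  # (n_cat, d)
    d = E.shape[1]
    W = rng.normal(0.0, spec.weight_scale, size=(d, spec.n_voxels))
    b = rng.normal(0.0, spec.intercept_scale, size=spec.n_voxels)
    noiseless = (E @ W + b).T  # (n_voxels, n_cat)

    nuis_features = nuis_weights = None
    if spec.nuisance is not None:
        ns = spec.nuisance
        base = rng.normal(size=(len(cats), ns.p))
        if ns.correlation != 0.0:
            proj = E @ rng.normal(size=(d, ns.p))
            proj = (proj - proj.mean(0)) / proj.std(0)
            base = (base - base.mean(0)) / base.std(0)
            base = ns.correlation * proj + np.sqrt(1 - ns.correlation**2) * base
        nuis_features = base
        nuis_weights = rng.normal(0.0, ns.weight_scale, size=(ns.p, spec.n_voxels))
        noiseless = noiseless + (nuis_features @ nuis_weights).T

    run_fold = np.repeat(np.arange(fold_design.n_folds), spec.n_runs_per_fold)
    cat_fold = np.array([fold_design.fold_of(c) for c in cats])
    n_runs = run_fold.size
    betas = np.full((spec.n_voxels, len(cats), n_runs), np.nan)
    for ri in range(n_runs):
        cols = np.flatnonzero(cat_fold == run_fold[ri])
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_voxels, cols.size))
        betas[:, cols, ri] = noiseless[:, cols] + noise
    data = ResponseData(
        [f"v{i:04d}" for i in range(spec.n_voxels)], fold_design, betas, run_fold
    )
    truth = {
        "weights": W,
        "intercepts": b,
        "noiseless": noiseless,
        "nuisance_features": nuis_features,
        "nuisance_weights": nuis_weights,
    }
    return data, truth


def generate_rating_panel(
    n_subjects: int,
    n_categories: int,
    true_scores: np.ndarray,
    rater_noise_sd: float = 0.5,
    n_outliers: int = 0,
    seed: int = 0,
    scale: tuple[float, float] = (1.0, 8.0),
    property_name: str = "size",
) -> tuple[RatingPanel, list[str]]:
    """Honest raters = true score + noise (rounded, clipped); outliers rate
    uniformly at random. Returns the panel and the outlier subject ids."""
    true_scores = np.asarray(true_scores, dtype=float)
    if true_scores.shape != (n_categories,):
        raise SpecError("true_scores must have one entry per category")
    lo, hi = scale
    if true_scores.min() < lo or true_scores.max() > hi:
        raise SpecError("true scores outside the rating scale")
    rng = np.random.default_rng(seed)
    subjects = [f"s{i:03d}" for i in range(n_subjects)]
    outliers = sorted(rng.choice(n_subjects, size=n_outliers, replace=False).tolist())
    outlier_ids = [subjects[i] for i in outliers]
    rows = np.empty((n_subjects, n_categories))
    for i in range(n_subjects):
        if i in outliers:
            rows[i] = rng.integers(int(lo), int(hi) + 1, size=n_categories)
        else:
            noisy = true_scores + rng.normal(0.0, rater_noise_sd, size=n_categories)
            rows[i] = np.clip(np.rint(noisy), lo, hi)
    panel = RatingPanel(
        pd.DataFrame(rows, index=subjects,
                     columns=[f"cat{i:03d}" for i in range(n_categories)]),
        property_name, scale,
    )
    return panel, outlier_ids


def write_spec(spec, path: str | Path) -> None:
    """Serialize a generator spec as JSON."""
    d = asdict(spec)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2)
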