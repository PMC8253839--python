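"""Stimulus-set optimization by RSA minimization.

Each experimental item receives one candidate nuisance-feature vector (a
"background") out of an open-ended pool; the goal is an assignment whose
nuisance-feature RDMs are as dissimilar as possible from the target models'
RDMs. The objective is ``r_max``: the maximum Spearman RSA correlation over
all target-model x nuisance-layer comparisons. Optimization is the classic
two-stage scheme: best of many random assignments over a pre-sampled
candidate pool, then single-item resampling hill climbing that accepts a
proposal only when it strictly lowers ``r_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import AlignmentError, DomainError, UndefinedDistanceError
from .semspace import RDM

__all__ = ["AssignmentState", "init_assignment", "optimize"]

#: A feature sampler returns one fresh candidate: a list of 1-D feature
#: vectors, one per feature layer (layer dimensions fixed across candidates).
FeatureSampler = Callable[[np.random.Generator], list[np.ndarray]]


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _centered_ranks(x: np.ndarray) -> np.ndarray:
    r = _rank(x)
    r -= r.mean()
    return r


@dataclass
class AssignmentState:
    """Current item-to-candidate assignment and the objective trace."""

    items: list[str]  # item identifiers
    item_category: np.ndarray  # (n_items,) index into categories
    categories: list[str]
    assignment: np.ndarray  # (n_items,) candidate index
    candidate_features: list[list[np.ndarray]]  # per candidate, per layer
    target_tri_ranks: list[np.ndarray]  # centered ranks of target RDM triangles
    r_max: float
    r_max_trace: list[float] = field(default_factory=list)
    seed: int = 0
    rng: np.random.Generator = None  # type: ignore[assignment]
    n_accepted: int = 0
    n_proposed: int = 0

    def nuisance_rdms(self) -> list[RDM]:
        """Per-layer RDMs of category-averaged assigned features."""
        mats = _category_features(self)
        out = []
        for M in mats:
            vals = 1.0 - np.corrcoef(M)
            np.fill_diagonal(vals, 0.0)
            out.append(RDM(self.categories, (vals + vals.T) / 2.0))
        return out


def _category_features(state: AssignmentState) -> list[np.ndarray]:
    """Average assigned candidate features within category, per layer."""
    n_cat = len(state.categories)
    counts = np.bincount(state.item_category, minlength=n_cat).astype(float)
    mats = []
    for layer in range(len(state.candidate_features[0])):
        dim = state.candidate_features[0][layer].size
        M = np.zeros((n_cat, dim))
        for i, cand in enumerate(state.assignment):
            M[state.item_category[i]] += state.candidate_features[cand][layer]
        mats.append(M / counts[:, None])
    return mats


def _evaluate_r_max(state: AssignmentState, assignment: np.ndarray) -> float:
    """r_max of an assignment: max Spearman over targets x nuisance layers."""
    saved = state.assignment
    state.assignment = assignment
    try:
        mats = _category_features(state)
    finally:
        state.assignment = saved
    n = len(state.categories)
    iu = np.triu_indices(n, k=1)
    best = -np.inf
    for M in mats:
        if np.any(np.ptp(M, axis=1) == 0):
            raise UndefinedDistanceError("constant category-averaged feature vector")
        vals = 1.0 - np.corrcoef(M)
        np.fill_diagonal(vals, 0.0)
        tri = ((vals + vals.T) / 2.0)[iu]  # bit-identical to the RDM path
        nr = _centered_ranks(tri)
        nr_norm = np.linalg.norm(nr)
        if nr_norm == 0:
            # constant RDM (e.g. one candidate shared by every category):
            # the Spearman comparison is undefined; never prefer this state
            return np.inf
        for tr in state.target_tri_ranks:
            rho = float(nr @ tr / (nr_norm * np.linalg.norm(tr)))
            if rho > best:
                best = rho
    return best


def init_assignment(
    items: Sequence[str],
    candidate_pool_size: int,
    n_random_assignments: int,
    target_rdms: Sequence[RDM],
    feature_sampler: FeatureSampler,
    seed: int,
    item_categories: Sequence[str] | None = None,
) -> AssignmentState:
    """Best-of-random initialization over a freshly sampled candidate pool.

    Parameters
    ----------
    items : item identifiers (e.g. individual stimulus images).
    item_categories : category of each item; defaults to the item itself,
        i.e. one item per category. Categories must match the target RDMs.
    """
    if candidate_pool_size < 1 or n_random_assignments < 1:
        raise DomainError("pool size and n_random_assignments must be >= 1")
    if not target_rdms:
        raise AlignmentError("need at least one target RDM")
    categories = target_rdms[0].categories
    for t in target_rdms:
        if t.categories != categories:
            raise AlignmentError("target RDMs must share categories")
    cats = list(items) if item_categories is None else list(item_categories)
    if len(cats) != len(items):
        raise AlignmentError("item_categories must align with items")
    cat_index = {c: i for i, c in enumerate(categories)}
    try:
        item_category = np.array([cat_index[c] for c in cats])
    except KeyError as exc:
        raise AlignmentError(f"item category not in target RDMs: {exc}") from None
    if set(item_category) != set(range(len(categories))):
        raise AlignmentError("every target category needs at least one item")

    rng = np.random.default_rng(seed)
    pool = [feature_sampler(rng) for _ in range(candidate_pool_size)]
    tri_ranks = [_centered_ranks(t.upper_triangle()) for t in target_rdms]

    state = AssignmentState(
        items=list(items),
        item_category=item_category,
        categories=list(categories),
        assignment=np.zeros(len(items), dtype=int),
        candidate_features=pool,
        target_tri_ranks=tri_ranks,
        r_max=np.inf,
        seed=seed,
        rng=rng,
    )
    best_assignment, best_r = None, np.inf
    for _ in range(n_random_assignments):
        cand = rng.integers(0, candidate_pool_size, size=len(items))
        r = _evaluate_r_max(state, cand)
        if r < best_r or best_assignment is None:
            best_assignment, best_r = cand, r
    state.assignment = best_assignment
    state.r_max = best_r
    state.r_max_trace = [best_r]
    return state


def optimize(
    state: AssignmentState,
    max_iterations: int,
    stop_threshold: float = -np.inf,
    feature_sampler: FeatureSampler | None = None,
) -> AssignmentState:
    """Single-item resampling hill climbing on ``r_max``.

    Each iteration resamples a fresh candidate for one uniformly chosen item
    and accepts the swap only if the new ``r_max`` is strictly lower than the
    current best. Stops at ``max_iterations`` proposals, or at the first
    accepted state with ``r_max`` below ``stop_threshold``. Without a
    ``feature_sampler`` proposals are drawn from the existing pool instead.
    """
    if state.r_max < stop_threshold:
        return state
    n_items = len(state.items)
    for _ in range(max_iterations):
        item = int(state.rng.integers(0, n_items))
        if feature_sampler is not None:
            state.candidate_features.append(feature_sampler(state.rng))
            cand = len(state.candidate_features) - 1
        else:
            cand = int(state.rng.integers(0, len(state.candidate_features)))
        proposal = state.assignment.copy()
        proposal[item] = cand
        state.n_proposed += 1
        r = _evaluate_r_max(state, proposal)
        if r < state.r_max:
            state.assignment = proposal
            state.r_max = r
            state.r_max_trace.append(r)
            state.n_accepted += 1
            if r < stop_threshold:
                break
        elif feature_sampler is not None:
            # rejected fresh candidate is unreferenced; keep the pool small
            state.candidate_features.pop()
    return state
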