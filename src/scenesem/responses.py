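"""Voxel response matrices: z-scoring, run averaging, split-half reliability.

The atomic measurement is a beta value: one regression amplitude per
(voxel, category, run). Categories are partitioned into disjoint folds and
each run presents exactly the categories of one fold, so the beta array is
structurally sparse: a (voxel, category, run) cell is defined only when the
category belongs to the run's fold. Within each run, responses are z-scored
across that run's categories. Split-half reliability (odd vs even runs) per
voxel serves as a noise-ceiling proxy and drives reliability masking via an
analytic critical correlation threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, CoverageError, DomainError, FormatError

__all__ = [
    "FoldDesign",
    "ResponseData",
    "VoxelMask",
    "zscore_within_run",
    "average_runs",
    "split_half_reliability",
    "critical_r",
    "reliability_mask",
    "read_betas_csv",
    "write_betas_csv",
]


@dataclass(frozen=True)
class FoldDesign:
    """Partition of the category set into disjoint folds."""

    folds: tuple[tuple[str, ...], ...]

    def __init__(self, folds: Sequence[Sequence[str]]) -> None:
        object.__setattr__(self, "folds", tuple(tuple(f) for f in folds))
        flat = [c for f in self.folds for c in f]
        if len(set(flat)) != len(flat):
            raise FormatError("folds must be disjoint")
        if any(len(f) == 0 for f in self.folds):
            raise FormatError("empty fold")

    @property
    def categories(self) -> list[str]:
        """Canonical category order: folds in order, categories within fold."""
        return [c for f in self.folds for c in f]

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def fold_of(self, category: str) -> int:
        for i, f in enumerate(self.folds):
            if category in f:
                return i
        raise AlignmentError(f"category not in fold design: {category!r}")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([list(f) for f in self.folds], fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldDesign":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh))


@dataclass
class ResponseData:
    """Beta values per (voxel, category, run) plus the fold/run structure.

    ``betas`` is (n_voxels, n_categories, n_runs) with NaN in cells whose
    category is not part of the run's fold. ``run_fold`` maps each run to
    its fold index.
    """

    voxels: list[str]
    fold_design: FoldDesign
    betas: np.ndarray
    run_fold: np.ndarray
    flagged_voxels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.run_fold = np.asarray(self.run_fold, dtype=int)
        cats = self.fold_design.categories
        n_v, n_c, n_r = self.betas.shape
        if n_v != len(self.voxels) or n_c != len(cats) or n_r != len(self.run_fold):
            raise FormatError("betas shape inconsistent with voxels/categories/runs")
        cat_fold = np.array([self.fold_design.fold_of(c) for c in cats])
        defined = ~np.isnan(self.betas).all(axis=0)
        expected = cat_fold[:, None] == self.run_fold[None, :]
        if not np.array_equal(defined, expected):
            raise FormatError("each run must contain exactly its fold's categories")

    @property
    def categories(self) -> list[str]:
        return self.fold_design.categories

    def runs_of_fold(self, fold: int) -> np.ndarray:
        """Run indices of one fold, in chronological (stored) order."""
        return np.flatnonzero(self.run_fold == fold)


def zscore_within_run(data: ResponseData) -> ResponseData:
    """Z-score each (voxel, run) slice across that run's categories.

    Uses the population standard deviation. Voxels with a constant slice are
    flagged (values set to NaN) and excluded downstream.
    """
    cats = data.categories
    cat_fold = np.array([data.fold_design.fold_of(c) for c in cats])
    out = data.betas.copy()
    flagged = set(data.flagged_voxels)
    for r in range(out.shape[2]):
        cols = np.flatnonzero(cat_fold == data.run_fold[r])
        slab = out[:, cols, r]
        mu = slab.mean(axis=1, keepdims=True)
        sd = slab.std(axis=1, keepdims=True)
        bad = (sd[:, 0] == 0) & ~np.isnan(sd[:, 0])
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, cols, r] = (slab - mu) / sd
        for i in np.flatnonzero(bad):
            flagged.add(data.voxels[i])
    for vid in flagged:
        out[data.voxels.index(vid)] = np.nan
    # flagged voxels keep the NaN pattern of defined cells for invariant checks
    result = ResponseData.__new__(ResponseData)
    result.voxels = list(data.voxels)
    result.fold_design = data.fold_design
    result.betas = out
    result.run_fold = data.run_fold.copy()
    result.flagged_voxels = flagged
    return result


def average_runs(data: ResponseData, run_subset: Sequence[int] | None = None) -> np.ndarray:
    """Per-voxel, per-category mean over the selected runs containing it."""
    runs = np.arange(data.betas.shape[2]) if run_subset is None else np.asarray(run_subset)
    sub = data.betas[:, :, runs]
    counts = (~np.isnan(sub)).any(axis=0).sum(axis=1)
    if np.any(counts == 0):
        missing = [data.categories[i] for i in np.flatnonzero(counts == 0)]
        raise CoverageError(f"categories absent from selected runs: {missing}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(sub, axis=2)


def split_half_reliability(data: ResponseData) -> np.ndarray:
    """Pearson correlation, per voxel, of odd-run vs even-run mean responses.

    Odd and even are defined on the 1-based chronological run position within
    each fold's run list. Voxels with an undefined half (constant or flagged)
    get NaN.
    """
    odd_runs, even_runs = [], []
    for f in range(data.fold_design.n_folds):
        runs = data.runs_of_fold(f)
        if len(runs) < 2:
            raise CoverageError(f"fold {f} needs at least one odd and one even run")
        odd_runs.extend(runs[0::2])
        even_runs.extend(runs[1::2])
    odd = average_runs(data, odd_runs)
    even = average_runs(data, even_runs)
    out = np.full(len(data.voxels), np.nan)
    for i in range(len(data.voxels)):
        u, v = odd[i], even[i]
        if np.isnan(u).any() or np.isnan(v).any() or np.ptp(u) == 0 or np.ptp(v) == 0:
            continue
        out[i] = np.corrcoef(u, v)[0, 1]
    return out


def critical_r(n: int, alpha: float) -> float:
    """Correlation whose one-sided p-value equals ``alpha`` under the null.

    Inverts the t-transform of the correlation coefficient:
    ``r = t / sqrt(t^2 + n - 2)`` with ``t`` the (1 - alpha) Student-t
    quantile at ``n - 2`` degrees of freedom.
    """
    if n < 3:
        raise DomainError("critical_r requires n >= 3")
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha, df=n - 2)
    return float(t / np.sqrt(t * t + n - 2))


@dataclass
class VoxelMask:
    """Voxels retained by a reliability threshold, with provenance."""

    voxels: list[str]
    threshold: float
    alpha: float | None
    reliability: dict[str, float]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text("\n".join(self.voxels) + "\n", encoding="utf-8")
        sidecar = {
            "threshold": self.threshold,
            "alpha": self.alpha,
            "reliability": self.reliability,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar), encoding="utf-8"
        )

    @classmethod
    def read(cls, path: str | Path) -> "VoxelMask":
        path = Path(path)
        voxels = [l for l in path.read_text(encoding="utf-8").splitlines() if l]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(voxels, meta["threshold"], meta["alpha"], meta["reliability"])


def reliability_mask(
    per_subject_reliabilities: Sequence[np.ndarray],
    voxels: Sequence[str],
    alpha: float | None = None,
    threshold: float | None = None,
    n_categories: int | None = None,
) -> VoxelMask:
    """Retain voxels whose cross-subject mean reliability meets the threshold.

    Give either an explicit ``threshold`` or an ``alpha`` (with
    ``n_categories``) from which the analytic critical r is derived. Voxels
    with undefined (NaN) reliability in any subject are excluded.
    """
    arrays = [np.asarray(a, dtype=float) for a in per_subject_reliabilities]
    if any(a.shape != (len(voxels),) for a in arrays):
        raise AlignmentError("per-subject reliabilities must align with voxels")
    if threshold is None:
        if alpha is None or n_categories is None:
            raise DomainError("give threshold, or alpha with n_categories")
        threshold = critical_r(n_categories, alpha)
    mean_rel = np.mean(arrays, axis=0)
    keep = ~np.isnan(mean_rel) & (mean_rel >= threshold)
    retained = [voxels[i] for i in np.flatnonzero(keep)]
    return VoxelMask(
        retained,
        float(threshold),
        alpha,
        {voxels[i]: float(mean_rel[i]) for i in np.flatnonzero(keep)},
    )


def write_betas_csv(data: ResponseData, path: str | Path) -> None:
    """Long-format CSV: one row per defined (voxel, category, run) cell."""
    cats = data.categories
    rows = []
    for vi, vid in enumerate(data.voxels):
        for ci, cat in enumerate(cats):
            for r in range(data.betas.shape[2]):
                val = data.betas[vi, ci, r]
                if data.fold_design.fold_of(cat) == data.run_fold[r]:
                    rows.append((vid, cat, r, val))
    pd.DataFrame(rows, columns=["voxel", "category", "run", "value"]).to_csv(
        path, index=False
    )


def read_betas_csv(path: str | Path, fold_design: FoldDesign) -> ResponseData:
    df = pd.read_csv(path)
    required = {"voxel", "category", "run", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"betas CSV needs columns {sorted(required)}")
    voxels = list(dict.fromkeys(df["voxel"].astype(str)))
    cats = fold_design.categories
    runs = sorted(df["run"].unique())
    vi = {v: i for i, v in enumerate(voxels)}
    ci = {c: i for i, c in enumerate(cats)}
    ri = {r: i for i, r in enumerate(runs)}
    betas = np.full((len(voxels), len(cats), len(runs)), np.nan)
    for row in df.itertuples(index=False):
        try:
            betas[vi[str(row.voxel)], ci[row.category], ri[row.run]] = row.value
        except KeyError:
            raise AlignmentError(f"unknown category {row.category!r}") from None
    run_fold = np.empty(len(runs), dtype=int)
    for r in runs:
        cats_in_run = df.loc[df["run"] == r, "category"].unique()
        folds = {fold_design.fold_of(c) for c in cats_in_run}
        if len(folds) != 1:
            raise FormatError(f"run {r} mixes categories from multiple folds")
        run_fold[ri[r]] = folds.pop()
    return ResponseData(voxels, fold_design, betas, run_fold)
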