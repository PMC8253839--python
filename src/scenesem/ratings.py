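"""Behavioral spatial-property ratings: outlier filtering and aggregation.

Crowdsourced raters score each object category on an ordinal scale
(real-world size 1-8, spatial stability 1-5). Because online raters cannot
be assumed attentive, subjects whose ratings disagree with the panel are
removed: a subject is dropped when their mean pairwise correlation with the
other subjects is more than ``sd_multiplier`` standard deviations away from
the mean of those per-subject means (a single, non-iterated pass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError

__all__ = ["RatingPanel", "filter_subjects", "aggregate", "spatial_design"]


@dataclass
class RatingPanel:
    """Subjects x categories matrix of ordinal ratings for one property."""

    ratings: pd.DataFrame  # index: subject ids, columns: categories
    property_name: str
    scale: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.scale
        values = self.ratings.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise DomainError("rating panel contains missing cells")
        if values.min() < lo or values.max() > hi:
            raise DomainError(
                f"ratings outside declared scale [{lo}, {hi}] for {self.property_name}"
            )

    @property
    def categories(self) -> list[str]:
        return list(self.ratings.columns)

    @property
    def subjects(self) -> list:
        return list(self.ratings.index)

    def to_csv(self, path: str | Path) -> None:
        self.ratings.to_csv(path, index_label="subject")

    @classmethod
    def from_csv(cls, path: str | Path, property_name: str,
                 scale: tuple[float, float]) -> "RatingPanel":
        df = pd.read_csv(path, index_col="subject")
        return cls(df, property_name, scale)


def filter_subjects(
    panel: RatingPanel, sd_multiplier: float = 1.5
) -> tuple[RatingPanel, list]:
    """Remove outlier raters by the mean-pairwise-correlation rule.

    Subjects with constant ratings (undefined correlations) are flagged and
    removed up front with a warning. With zero dispersion across the
    remaining per-subject means, nobody is removed.
    """
    if len(panel.subjects) < 3:
        raise DomainError("subject filtering requires at least 3 subjects")
    X = panel.ratings.to_numpy(dtype=float)
    constant = np.ptp(X, axis=1) == 0
    removed = [s for s, c in zip(panel.subjects, constant) if c]
    if removed:
        warnings.warn(
            f"subjects with constant ratings removed: {removed}", stacklevel=2
        )
    keep_idx = np.flatnonzero(~constant)
    Xv = X[keep_idx]
    corr = np.corrcoef(Xv)
    n = len(keep_idx)
    mean_pair = (corr.sum(axis=1) - 1.0) / (n - 1)
    sd = mean_pair.std(ddof=1)
    if sd > 0:
        dev = np.abs(mean_pair - mean_pair.mean())
        outlier = dev > sd_multiplier * sd
    else:
        outlier = np.zeros(n, dtype=bool)
    removed += [panel.subjects[keep_idx[i]] for i in np.flatnonzero(outlier)]
    retained_subjects = [panel.subjects[keep_idx[i]] for i in np.flatnonzero(~outlier)]
    retained = RatingPanel(
        panel.ratings.loc[retained_subjects], panel.property_name, panel.scale
    )
    return retained, removed


def aggregate(panel: RatingPanel) -> pd.Series:
    """Unweighted per-category mean rating over the panel's subjects."""
    if len(panel.subjects) == 0:
        raise DomainError("cannot aggregate an empty panel")
    return panel.ratings.mean(axis=0)


def spatial_design(size_means: pd.Series, stability_means: pd.Series) -> pd.DataFrame:
    """Two-column model matrix (size, stability), categories as rows.

    The ratings are passed through unscaled; any centering happens at the
    encoding stage.
    """
    if list(size_means.index) != list(stability_means.index):
        raise AlignmentError("size and stability category orders differ")
    return pd.DataFrame(
        {"size": size_means.to_numpy(), "stability": stability_means.to_numpy()},
        index=size_means.index,
    )
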