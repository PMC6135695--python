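"""Marker-gene classification by per-epigenotype mean-beta thresholds.

A high-CpG gene is "methylated" in an epigenotype when its mean beta over that
epigenotype's samples is at or above the threshold (default 0.2), and
"unmethylated" strictly below it.  The four marker classes are the nested
methylation patterns across HME > IME > LME > NME:

========================  ====  ====  ====  ====
class                      HME   IME   LME   NME
========================  ====  ====  ====  ====
high markers               >=t   <t    <t    <t
intermediate markers       >=t   >=t   <t    <t
common markers             >=t   >=t   >=t   <t
normally methylated        >=t   >=t   >=t   >=t
========================  ====  ====  ====  ====

Genes matching no row are unclassified.  Group comparisons pool the per-gene,
per-sample beta-values of a marker set within each group and report mean,
standard error and a pooled-variance two-sided Student's t-test.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .clustering import FOUR_EPIGENOTYPES, EpigenotypeAssignment
from .io import BetaMatrix, InputError

__all__ = [
    "MarkerSets",
    "GroupComparison",
    "per_me_means",
    "extract_marker_genes",
    "compare_marker_methylation",
    "MarkerGeneExtractor",
    "MARKER_CLASSES",
]

MARKER_CLASSES = ("high", "intermediate", "common", "normal")

# methylated-pattern per class over (HME, IME, LME, NME)
_PATTERNS = {
    "high": (True, False, False, False),
    "intermediate": (True, True, False, False),
    "common": (True, True, True, False),
    "normal": (True, True, True, True),
}


@dataclasses.dataclass
class MarkerSets:
    """The four disjoint marker-gene classes plus the mean table they derive from."""

    high_markers: frozenset[str]
    intermediate_markers: frozenset[str]
    common_markers: frozenset[str]
    normal_markers: frozenset[str]
    mean_table: pd.DataFrame
    threshold: float

    def __getitem__(self, marker_class: str) -> frozenset[str]:
        try:
            return getattr(self, f"{marker_class}_markers")
        except AttributeError:
            raise KeyError(marker_class) from None

    @property
    def classes(self) -> pd.Series:
        """Per-gene class label ('unclassified' for genes matching no pattern)."""
        labels = pd.Series("unclassified", index=self.mean_table.index, name="marker_class")
        for cls in MARKER_CLASSES:
            labels[list(self[cls])] = cls
        return labels

    def counts(self) -> dict[str, int]:
        return {cls: len(self[cls]) for cls in MARKER_CLASSES}


@dataclasses.dataclass
class GroupComparison:
    """Pooled-beta comparison of one marker class between two sample groups."""

    marker_class: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float


def _assignment_labels(assignments: EpigenotypeAssignment | pd.Series) -> pd.Series:
    if isinstance(assignments, EpigenotypeAssignment):
        return assignments.labels
    return assignments


def per_me_means(matrix: BetaMatrix | pd.DataFrame,
                 assignments: EpigenotypeAssignment | pd.Series,
                 samples: Iterable[str] | None = None,
                 epigenotypes: Sequence[str] = FOUR_EPIGENOTYPES) -> pd.DataFrame:
    """Per-gene (selected-probe), per-epigenotype arithmetic mean beta.

    ``samples`` restricts the computation to a cohort (the marker definition
    uses sporadic CRC only); missing values are excluded per cell.  An
    epigenotype with no samples in the filter, or a gene with no non-missing
    value in some epigenotype, is an error.
    """
    values = matrix.values if isinstance(matrix, BetaMatrix) else matrix
    labels = _assignment_labels(assignments)
    if samples is not None:
        samples = [s for s in samples if s in labels.index]
        labels = labels.loc[samples]
    labels = labels[labels.index.isin(values.columns)]
    table = {}
    for me in epigenotypes:
        group = list(labels.index[labels == me])
        if not group:
            raise InputError(f"no samples with epigenotype {me!r} in the filtered cohort")
        sub = values[group]
        counts = sub.notna().sum(axis=1)
        if (counts == 0).any():
            gene = counts.index[counts == 0][0]
            raise InputError(f"gene {gene!r} has no non-missing value in epigenotype {me!r}")
        table[me] = sub.mean(axis=1)
    out = pd.DataFrame(table)[list(epigenotypes)]
    out.index.name = "gene"
    return out


def extract_marker_genes(mean_table: pd.DataFrame, threshold: float = 0.2) -> MarkerSets:
    """Classify genes into the four marker classes from a per-ME mean table.

    ``mean_table`` is genes x (HME, IME, LME, NME).  Methylated means
    ``mean >= threshold``; unmethylated is the strict complement, so every
    gene is classifiable and the classes are disjoint by construction.
    """
    missing = [me for me in FOUR_EPIGENOTYPES if me not in mean_table.columns]
    if missing:
        raise InputError(f"mean table lacks epigenotype columns: {missing}")
    methylated = mean_table[list(FOUR_EPIGENOTYPES)] >= threshold
    sets = {}
    for cls, pattern in _PATTERNS.items():
        mask = np.ones(len(mean_table), dtype=bool)
        for me, want in zip(FOUR_EPIGENOTYPES, pattern):
            mask &= (methylated[me] == want).to_numpy()
        sets[cls] = frozenset(mean_table.index[mask])
    return MarkerSets(high_markers=sets["high"], intermediate_markers=sets["intermediate"],
                      common_markers=sets["common"], normal_markers=sets["normal"],
                      mean_table=mean_table.copy(), threshold=threshold)


def compare_marker_methylation(matrix: BetaMatrix | pd.DataFrame,
                               genes: Iterable[str],
                               samples_a: Sequence[str],
                               samples_b: Sequence[str],
                               group_a: str = "A",
                               group_b: str = "B",
                               marker_class: str = "") -> GroupComparison:
    """Compare pooled marker beta-values between two sample groups.

    Pools every (gene, sample) beta within each group, reports group mean and
    standard error (SD/sqrt(n) of the pooled values) and a two-sided
    pooled-variance Student's t-test.
    """
    values = matrix.values if isinstance(matrix, BetaMatrix) else matrix
    genes = list(genes)
    if not genes:
        raise InputError("empty marker gene set")
    if not len(samples_a) or not len(samples_b):
        raise InputError("both sample groups must be non-empty")
    pooled = []
    for group in (list(samples_a), list(samples_b)):
        missing = [s for s in group if s not in values.columns]
        if missing:
            raise InputError(f"samples absent from matrix: {missing[:5]}")
        flat = values.loc[genes, group].to_numpy().ravel()
        flat = flat[~np.isnan(flat)]
        if flat.size < 2:
            raise InputError("fewer than 2 pooled values in a group")
        pooled.append(flat)
    a, b = pooled
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        marker_class=marker_class, group_a=group_a, group_b=group_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        se_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        se_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        n_a=int(a.size), n_b=int(b.size),
        t_statistic=float(t_stat), p_value=float(p))


class MarkerGeneExtractor(BaseEstimator):
    """Estimator form of threshold marker extraction.

    ``fit`` takes the genes x epigenotype mean-beta table; fitted attributes
    expose the four marker classes.

    Attributes
    ----------
    marker_sets_ : MarkerSets
    classes_ : pandas.Series
        Per-gene class label ('unclassified' when no pattern matches).
    """

    def __init__(self, beta_threshold: float = 0.2):
        self.beta_threshold = beta_threshold

    def fit(self, mean_table: pd.DataFrame, y=None):
        self.marker_sets_ = extract_marker_genes(mean_table, threshold=self.beta_threshold)
        self.classes_ = self.marker_sets_.classes
        return self

    def predict(self, mean_table: pd.DataFrame) -> np.ndarray:
        """Class labels for a new mean table at the fitted threshold."""
        return extract_marker_genes(mean_table, threshold=self.beta_threshold).classes.to_numpy()
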