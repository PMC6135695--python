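"""The probe-filter cascade that defines the analysis probe set.

Four stages, applied in order:

1. FFPE concordance — keep probes whose beta-value differs by strictly less
   than ``delta_beta_threshold`` between the frozen and FFPE member of every
   paired tumor (intersection over pairs).  Probes unaffected by fixation
   artifacts can then be measured on either preparation.
2. Promoter probe selection — when several probes fall in one gene's promoter,
   keep the single probe nearest the transcription start site.
3. High-CpG gene definition — keep genes whose selected probe sits in CpG-rich
   sequence: observed/expected CpG ratio of the 500-bp window (+/-250 bp around
   the probe) strictly above ``cpg_score_threshold``.
4. Variance filter — keep probes whose across-sample beta SD (n-1 denominator)
   strictly exceeds ``sd_threshold``; constant probes carry no subtype signal.

All boundary comparisons are strict, as printed in the thresholds' sources.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import BetaMatrix, InputError

__all__ = [
    "ConcordanceResult",
    "GenePromoterProbe",
    "concordant_probes",
    "cpg_score",
    "select_promoter_probe",
    "select_promoter_probes",
    "high_cpg_genes",
    "variance_filter",
    "FFPEConcordanceFilter",
    "HighCpGSelector",
    "BetaVarianceFilter",
]


@dataclasses.dataclass
class ConcordanceResult:
    """Per-pair concordant probe sets and their intersection."""

    per_pair: list[frozenset[str]]
    intersection: frozenset[str]

    @property
    def per_pair_counts(self) -> list[int]:
        return [len(s) for s in self.per_pair]


@dataclasses.dataclass(frozen=True)
class GenePromoterProbe:
    """The single promoter probe retained for a gene."""

    gene: str
    probe_id: str
    tss_distance: int
    cpg_score: float | None = None


def concordant_probes(pairs: Sequence[tuple[pd.Series, pd.Series]],
                      threshold: float = 0.1) -> ConcordanceResult:
    """Probes concordant (|beta_frozen - beta_FFPE| strictly < threshold) in every pair.

    Each pair is (frozen, FFPE) beta vectors indexed by a shared probe
    universe.  A probe with a missing value in either member of a pair is
    non-concordant for that pair.
    """
    if threshold <= 0:
        raise InputError("concordance threshold must be > 0")
    if len(pairs) == 0:
        raise InputError("at least one frozen/FFPE pair is required")
    universe = pairs[0][0].index
    per_pair: list[frozenset[str]] = []
    for i, (frozen, ffpe) in enumerate(pairs):
        if not (frozen.index.equals(universe) and ffpe.index.equals(universe)):
            raise InputError(f"pair {i} does not cover the shared probe universe")
        diff = (frozen - ffpe).abs()
        keep = diff[diff < threshold].index  # NaN diffs drop out: missing => non-concordant
        per_pair.append(frozenset(keep))
    intersection = frozenset.intersection(*per_pair)
    return ConcordanceResult(per_pair=per_pair, intersection=intersection)


def cpg_score(window_sequence: str) -> float:
    """Observed/expected CpG ratio of a sequence window.

    ``N_CpG / (N_C * N_G / L)`` where ``N_CpG`` counts CG dinucleotides,
    ``N_C``/``N_G`` count bases, and ``L`` is the number of counted (non-N)
    bases.  Returns 0.0 when the window contains no C or no G.  The score is
    strand-symmetric: CG reverse-complements to CG.
    """
    if not window_sequence:
        raise InputError("empty window sequence")
    seq = window_sequence.upper()
    extra = set(seq) - set("ACGTN")
    if extra:
        raise InputError(f"illegal characters in window sequence: {sorted(extra)}")
    length = len(seq) - seq.count("N")
    if length < 2:
        raise InputError("window must contain at least 2 counted bases")
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c * n_g == 0:
        return 0.0
    n_cpg = seq.count("CG")
    return n_cpg / (n_c * n_g / length)


def select_promoter_probe(gene: str,
                          candidates: Mapping[str, int] | pd.Series,
                          tss_position: int) -> GenePromoterProbe:
    """Pick the candidate probe nearest the TSS; ties go to the smaller coordinate."""
    if isinstance(candidates, pd.Series):
        candidates = candidates.to_dict()
    if not candidates:
        raise InputError(f"gene {gene!r} has no candidate promoter probes")
    best = min(candidates.items(), key=lambda kv: (abs(kv[1] - tss_position), kv[1], kv[0]))
    return GenePromoterProbe(gene=gene, probe_id=best[0],
                             tss_distance=abs(best[1] - tss_position))


def select_promoter_probes(annotation: pd.DataFrame) -> pd.DataFrame:
    """One promoter probe per gene over a full annotation table.

    Returns a DataFrame indexed by gene with columns ``probe_id``,
    ``tss_distance`` and ``cpg_score`` (NaN when the annotation provides
    neither a precomputed score nor a window sequence).
    """
    scores = _annotation_scores(annotation)
    rows = []
    for gene, group in annotation.groupby("gene", sort=True):
        tss = int(group["tss_position"].iloc[0])
        chosen = select_promoter_probe(gene, group["position"], tss)
        rows.append({"gene": gene, "probe_id": chosen.probe_id,
                     "tss_distance": chosen.tss_distance,
                     "cpg_score": scores.get(chosen.probe_id, np.nan)})
    return pd.DataFrame(rows).set_index("gene")


def _annotation_scores(annotation: pd.DataFrame) -> dict[str, float]:
    """Per-probe CpG score: precomputed column if present, else counted from the window."""
    scores: dict[str, float] = {}
    if "cpg_score" in annotation.columns:
        scores.update(annotation["cpg_score"].dropna().to_dict())
    if "window_sequence" in annotation.columns:
        for probe, seq in annotation["window_sequence"].dropna().items():
            if probe not in scores:
                scores[probe] = cpg_score(seq)
    return scores


def high_cpg_genes(annotation: pd.DataFrame, threshold: float = 0.48) -> pd.DataFrame:
    """Genes whose selected promoter probe has CpG score strictly above ``threshold``.

    Returns the :func:`select_promoter_probes` table restricted to qualifying
    genes.  A gene whose selected probe has no score (no precomputed value and
    no window sequence) is an error.
    """
    selected = select_promoter_probes(annotation)
    missing = selected.index[selected["cpg_score"].isna()].tolist()
    if missing:
        raise InputError(f"genes lacking a CpG score for their selected probe: {missing[:5]}")
    return selected[selected["cpg_score"] > threshold]


def variance_filter(matrix: BetaMatrix | pd.DataFrame, sd_threshold: float = 0.10) -> list[str]:
    """Probes whose across-sample SD (ddof=1, missing excluded) strictly exceeds the threshold."""
    values = matrix.values if isinstance(matrix, BetaMatrix) else matrix
    counts = values.notna().sum(axis=1)
    if (counts < 2).any():
        probe = counts.index[counts < 2][0]
        raise InputError(f"probe {probe!r} has fewer than 2 non-missing values")
    sd = values.std(axis=1, ddof=1)
    return list(sd.index[sd > sd_threshold])


class FFPEConcordanceFilter(BaseEstimator, TransformerMixin):
    """Transformer dropping probes discordant between frozen and FFPE pairs.

    Parameters
    ----------
    threshold : float, default=0.1
        Strict |delta beta| bound for per-pair concordance.

    Attributes
    ----------
    result_ : ConcordanceResult
        Per-pair sets and intersection learned by :meth:`fit`.
    concordant_probes_ : frozenset of str
        The intersection over pairs; the probe universe :meth:`transform` keeps.
    """

    def __init__(self, threshold: float = 0.1):
        self.threshold = threshold

    def fit(self, pairs: Sequence[tuple[pd.Series, pd.Series]], y=None):
        self.result_ = concordant_probes(pairs, threshold=self.threshold)
        self.concordant_probes_ = self.result_.intersection
        return self

    def transform(self, X: BetaMatrix | pd.DataFrame) -> pd.DataFrame:
        values = X.values if isinstance(X, BetaMatrix) else X
        keep = [p for p in values.index if p in self.concordant_probes_]
        return values.loc[keep]


class HighCpGSelector(BaseEstimator, TransformerMixin):
    """Transformer restricting a beta matrix to high-CpG genes' promoter probes.

    Parameters
    ----------
    score_threshold : float, default=0.48
        Strict observed/expected CpG ratio bound.

    Attributes
    ----------
    genes_ : pandas.DataFrame
        Qualifying genes with their selected probe, TSS distance and score.
    selected_probes_ : list of str
        The one-per-gene probe ids :meth:`transform` keeps.
    """

    def __init__(self, score_threshold: float = 0.48):
        self.score_threshold = score_threshold

    def fit(self, annotation: pd.DataFrame, y=None):
        self.genes_ = high_cpg_genes(annotation, threshold=self.score_threshold)
        self.selected_probes_ = list(self.genes_["probe_id"])
        self.probe_to_gene_ = dict(zip(self.genes_["probe_id"], self.genes_.index))
        return self

    def transform(self, X: BetaMatrix | pd.DataFrame) -> pd.DataFrame:
        values = X.values if isinstance(X, BetaMatrix) else X
        keep = [p for p in self.selected_probes_ if p in values.index]
        return values.loc[keep]


class BetaVarianceFilter(BaseEstimator, TransformerMixin):
    """Transformer keeping probes whose sample SD strictly exceeds ``sd_threshold``."""

    def __init__(self, sd_threshold: float = 0.10):
        self.sd_threshold = sd_threshold

    def fit(self, X: BetaMatrix | pd.DataFrame, y=None):
        self.selected_probes_ = variance_filter(X, sd_threshold=self.sd_threshold)
        return self

    def transform(self, X: BetaMatrix | pd.DataFrame) -> pd.DataFrame:
        values = X.values if isinstance(X, BetaMatrix) else X
        keep = [p for p in values.index if p in set(self.selected_probes_)]
        return values.loc[keep]
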