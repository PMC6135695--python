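"""Two-way hierarchical clustering and methylation-epigenotype assignment.

Samples are clustered with Pearson correlation distance (1 - r) and average
(UPGMA) linkage; marker probes with city-block (Manhattan) distance and
complete linkage.  The sample tree is cut into ``n_clusters`` flat clusters,
clusters are ranked by their mean beta over the clustering probes, and labels
are assigned in descending order: HME, IME, LME, NME for the four-epigenotype
cut; IME, NME for the two-subtype (FAP confirmation) cut.

When normal-mucosa samples are supplied, the lowest-methylation cluster must
hold the majority (>50%) of them — that is what makes it "normal-like" — and
a violation raises :class:`EpigenotypeError` rather than silently mislabeling.

An optional smallest-cluster outlier rule (``min_cluster_size``) flags
clusters below the minimum size as outliers and re-cuts the remaining samples,
so a single aberrant profile cannot consume one of the k clusters.

Samples and probes are canonically sorted by id before any distance is
computed, which makes results invariant to input ordering and byte-identical
across runs.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin

from .io import BetaMatrix, InputError

__all__ = [
    "EpigenotypeError",
    "EpigenotypeAssignment",
    "EpigenotypeClusterer",
    "two_way_cluster",
    "assign_epigenotypes",
    "recluster_subset",
    "linkage_to_newick",
    "FOUR_EPIGENOTYPES",
    "TWO_SUBTYPES",
]

FOUR_EPIGENOTYPES = ("HME", "IME", "LME", "NME")
TWO_SUBTYPES = ("IME", "NME")

_SAMPLE_METRICS = {"correlation": "correlation", "uncentered": "cosine"}


class EpigenotypeError(RuntimeError):
    """Clustering output inconsistent with the epigenotype model."""


@dataclasses.dataclass
class EpigenotypeAssignment:
    """Flat epigenotype labels plus the dendrograms they were cut from.

    ``labels`` maps every non-outlier sample to its epigenotype; outliers are
    listed in ``outliers`` and absent from ``labels``.  ``cluster_means`` maps
    each label to the cluster's mean beta over ``probes`` (strictly descending
    in canonical label order).
    """

    labels: pd.Series
    cluster_index: pd.Series
    outliers: list[str]
    sample_linkage: np.ndarray
    probe_linkage: np.ndarray | None
    sample_order: list[str]
    probes: list[str]
    cluster_means: pd.Series

    def samples_with_label(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"epigenotype": self.labels,
                              "cluster": self.cluster_index.reindex(self.labels.index)})
        if self.outliers:
            out = pd.DataFrame({"epigenotype": "outlier", "cluster": pd.NA},
                               index=pd.Index(self.outliers, name=frame.index.name))
            frame = pd.concat([frame, out])
        frame.index.name = "sample_id"
        return frame.sort_index()


def _as_values(matrix: BetaMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, BetaMatrix) else matrix


def _check_complete(values: pd.DataFrame) -> None:
    if values.isna().any().any():
        probe = values.index[values.isna().any(axis=1)][0]
        raise InputError(f"clustering requires a complete matrix; probe {probe!r} has missing values")


def _sample_distances(samples_by_probes: np.ndarray, metric: str) -> np.ndarray:
    if metric not in _SAMPLE_METRICS:
        raise InputError(f"unknown sample metric {metric!r}; use 'correlation' or 'uncentered'")
    if metric == "correlation":
        sds = samples_by_probes.std(axis=1)
        if np.any(sds == 0):
            raise EpigenotypeError("zero-variance sample: correlation distance undefined")
    return pdist(samples_by_probes, metric=_SAMPLE_METRICS[metric])


def two_way_cluster(matrix: BetaMatrix | pd.DataFrame,
                    sample_metric: str = "correlation",
                    sample_linkage: str = "average",
                    probe_metric: str = "cityblock",
                    probe_linkage: str = "complete",
                    ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Cluster samples and probes of a probe x sample matrix.

    Returns ``(sample_Z, probe_Z, sample_order, probe_order)`` where the
    linkage matrices are in scipy format over the canonically (id-) sorted
    orders.
    """
    values = _as_values(matrix)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise InputError("two-way clustering needs at least 2 probes and 2 samples")
    _check_complete(values)
    values = values.sort_index(axis=0).sort_index(axis=1)
    sample_order = list(values.columns)
    probe_order = list(values.index)
    sample_z = linkage(_sample_distances(values.to_numpy().T, sample_metric),
                       method=sample_linkage)
    probe_z = linkage(pdist(values.to_numpy(), metric=probe_metric), method=probe_linkage)
    return sample_z, probe_z, sample_order, probe_order


def _labels_for_k(k: int, labels: Sequence[str] | None) -> list[str]:
    if labels is not None:
        if len(labels) != k:
            raise InputError(f"{len(labels)} labels supplied for k={k}")
        return list(labels)
    if k == 4:
        return list(FOUR_EPIGENOTYPES)
    if k == 2:
        return list(TWO_SUBTYPES)
    return [f"ME{i + 1}" for i in range(k)]


def _cut_and_label(values: pd.DataFrame, sample_z: np.ndarray, sample_order: list[str],
                   k: int, label_names: list[str],
                   ) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Cut a sample tree into k clusters and label them by descending mean beta."""
    flat = fcluster(sample_z, t=k, criterion="maxclust")
    if len(set(flat)) < k:
        raise EpigenotypeError(f"tree cut produced {len(set(flat))} < {k} clusters")
    cluster_index = pd.Series(flat, index=sample_order, name="cluster")
    means = values.loc[:, sample_order].mean(axis=0).groupby(cluster_index).mean()
    if means.round(12).duplicated().any():
        raise EpigenotypeError("tie in cluster mean beta; epigenotype ranking is ambiguous")
    ranked = means.sort_values(ascending=False)
    label_of_cluster = {cl: label_names[i] for i, cl in enumerate(ranked.index)}
    labels = cluster_index.map(label_of_cluster).rename("epigenotype")
    cluster_means = pd.Series({label_names[i]: ranked.iloc[i] for i in range(k)})
    return labels, cluster_index, cluster_means


def assign_epigenotypes(matrix: BetaMatrix | pd.DataFrame,
                        metadata: pd.DataFrame | None = None,
                        k: int = 4,
                        min_cluster_size: int | None = None,
                        sample_metric: str = "correlation",
                        labels: Sequence[str] | None = None,
                        ) -> EpigenotypeAssignment:
    """Two-way cluster a marker matrix and assign per-sample epigenotype labels.

    ``matrix`` is probes x samples, restricted to the clustering probes.
    ``metadata`` (indexed by sample id with a ``cohort`` column) enables the
    normal-mucosa consistency check: when normals are present, the
    lowest-methylation cluster must contain more than half of them.
    """
    values = _as_values(matrix)
    label_names = _labels_for_k(k, labels)
    sample_z, probe_z, sample_order, probe_order = two_way_cluster(
        values, sample_metric=sample_metric)

    outliers: list[str] = []
    current = values.sort_index(axis=0).sort_index(axis=1)
    flat_labels, cluster_index, cluster_means = _cut_and_label(
        current, sample_z, sample_order, k, label_names)
    if min_cluster_size is not None and min_cluster_size > 1:
        # single outlier pass: flag small clusters, re-cut the remainder once
        sizes = cluster_index.value_counts()
        small = sizes.index[sizes < min_cluster_size]
        if not small.empty:
            outliers = list(cluster_index.index[cluster_index.isin(small)])
            current = current.drop(columns=outliers)
            remaining = [s for s in sample_order if s not in set(outliers)]
            if len(remaining) < k:
                raise EpigenotypeError(
                    f"only {len(remaining)} samples remain after outlier removal; need >= {k}")
            recut_z = linkage(_sample_distances(current.to_numpy().T, sample_metric),
                              method="average")
            flat_labels, cluster_index, cluster_means = _cut_and_label(
                current, recut_z, remaining, k, label_names)

    if metadata is not None and "cohort" in metadata.columns:
        normals = [s for s in flat_labels.index
                   if s in metadata.index and metadata.loc[s, "cohort"] == "normal"]
        if normals:
            lowest = label_names[k - 1]
            in_lowest = sum(flat_labels[s] == lowest for s in normals)
            if in_lowest * 2 <= len(normals):
                raise EpigenotypeError(
                    f"normal-sample check failed: {in_lowest}/{len(normals)} normals in the "
                    f"lowest-methylation cluster ({lowest}); majority required")

    return EpigenotypeAssignment(
        labels=flat_labels, cluster_index=cluster_index, outliers=sorted(outliers),
        sample_linkage=sample_z, probe_linkage=probe_z, sample_order=sample_order,
        probes=probe_order, cluster_means=cluster_means)


def recluster_subset(matrix: BetaMatrix | pd.DataFrame,
                     samples: Iterable[str],
                     k: int = 2,
                     min_cluster_size: int = 2,
                     metadata: pd.DataFrame | None = None,
                     sample_metric: str = "correlation",
                     ) -> EpigenotypeAssignment:
    """Re-cluster a sample subset (two-subtype mode by default).

    Cuts at ``k``; clusters smaller than ``min_cluster_size`` are flagged as
    outliers and the remaining samples re-cut.  For ``k=2`` the higher-mean
    cluster is labeled IME and the lower NME.
    """
    values = _as_values(matrix)
    samples = list(samples)
    missing = [s for s in samples if s not in values.columns]
    if missing:
        raise InputError(f"subset samples absent from matrix: {missing[:5]}")
    return assign_epigenotypes(values[samples], metadata=metadata, k=k,
                               min_cluster_size=min_cluster_size,
                               sample_metric=sample_metric)


def linkage_to_newick(z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with merge-height branch lengths."""
    tree = to_tree(z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


class EpigenotypeClusterer(BaseEstimator, ClusterMixin):
    """Hierarchical epigenotype clusterer in scikit-learn estimator form.

    Follows the sklearn convention that ``X`` rows are observations: fit takes
    a samples x probes DataFrame (the transpose of the on-disk beta matrix).

    Parameters
    ----------
    n_clusters : int, default=4
        Number of flat clusters cut from the sample tree.
    min_cluster_size : int or None, default=None
        When set, clusters smaller than this are flagged outliers and the
        remaining samples re-cut.
    sample_metric : {"correlation", "uncentered"}, default="correlation"
        Centered Pearson correlation distance, or the uncentered (cosine)
        variant.
    label_names : sequence of str or None
        Override the label set (defaults: HME/IME/LME/NME at k=4, IME/NME at
        k=2).

    Attributes
    ----------
    assignment_ : EpigenotypeAssignment
    labels_ : ndarray of str
        Per-row label aligned with the input rows ("outlier" for flagged rows).
    epigenotypes_ : pandas.Series
        Label per sample id (non-outliers only).
    cluster_means_ : pandas.Series
        Mean beta per label, strictly descending in label order.
    """

    def __init__(self, n_clusters: int = 4, min_cluster_size: int | None = None,
                 sample_metric: str = "correlation",
                 label_names: Sequence[str] | None = None):
        self.n_clusters = n_clusters
        self.min_cluster_size = min_cluster_size
        self.sample_metric = sample_metric
        self.label_names = label_names

    def fit(self, X: pd.DataFrame, y=None, metadata: pd.DataFrame | None = None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X),
                             index=[f"s{i}" for i in range(np.asarray(X).shape[0])])
        self.assignment_ = assign_epigenotypes(
            X.T, metadata=metadata, k=self.n_clusters,
            min_cluster_size=self.min_cluster_size, sample_metric=self.sample_metric,
            labels=self.label_names)
        frame = self.assignment_.to_frame()
        self.labels_ = frame.loc[list(X.index), "epigenotype"].to_numpy()
        self.epigenotypes_ = self.assignment_.labels
        self.cluster_means_ = self.assignment_.cluster_means
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).labels_
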