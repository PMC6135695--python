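"""Hierarchical clustering against a naive oracle, and epigenotype assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from sklearn.metrics import adjusted_rand_score

from conftest import naive_hierarchical
from epigenotyper.clustering import (EpigenotypeClusterer, EpigenotypeError,
                                     assign_epigenotypes, linkage_to_newick,
                                     recluster_subset, two_way_cluster)
from epigenotyper.io import InputError
from epigenotyper.synthetic import CohortConfig, generate_cohort


def _matrix(data, probes=None, samples=None):
    data = np.asarray(data, dtype=float)
    probes = probes or [f"g{i}" for i in range(data.shape[0])]
    samples = samples or [f"s{j}" for j in range(data.shape[1])]
    return pd.DataFrame(data, index=probes, columns=samples)


class TestTwoWayCluster:
    def test_identical_samples_merge_at_zero(self):
        values = _matrix(np.tile(np.linspace(0.1, 0.9, 5)[:, None], (1, 3)))
        z, _, order, _ = two_way_cluster(values)
        assert z[:, 2] == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_two_planted_blocks_merge_within_first(self):
        rng = np.random.default_rng(0)
        profile_a = rng.uniform(0, 1, 20)
        profile_b = 1 - profile_a
        cols = np.column_stack([profile_a + rng.normal(0, 0.01, 20),
                                profile_a + rng.normal(0, 0.01, 20),
                                profile_b + rng.normal(0, 0.01, 20),
                                profile_b + rng.normal(0, 0.01, 20)])
        z, _, order, _ = two_way_cluster(_matrix(cols))
        # first two merges join within-block pairs (leaves {0,1} and {2,3})
        first_pairs = {frozenset(map(int, row[:2])) for row in z[:2]}
        assert first_pairs == {frozenset({0, 1}), frozenset({2, 3})}

    def test_zero_variance_sample_rejected(self):
        values = _matrix([[0.5, 0.1], [0.5, 0.9]])
        with pytest.raises(EpigenotypeError, match="zero-variance"):
            two_way_cluster(values)

    def test_missing_values_rejected(self):
        values = _matrix([[0.5, np.nan], [0.4, 0.9]])
        with pytest.raises(InputError, match="missing"):
            two_way_cluster(values)

    @pytest.mark.parametrize("n_leaves", [3, 4, 5, 6])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_oracle(self, n_leaves, seed):
        """Merge heights and cophenetic structure equal the exhaustive oracle."""
        rng = np.random.default_rng(100 * n_leaves + seed)
        values = _matrix(rng.uniform(0, 1, size=(8, n_leaves)))
        z_samples, z_probes, sample_order, probe_order = two_way_cluster(values)

        X_samples = values[sample_order].to_numpy().T
        heights, coph_naive = naive_hierarchical(X_samples, "correlation", "average")
        np.testing.assert_allclose(sorted(z_samples[:, 2]), sorted(heights), rtol=1e-10)
        np.testing.assert_allclose(_coph_matrix(z_samples, n_leaves), coph_naive, rtol=1e-10)

        X_probes = values.loc[probe_order].to_numpy()
        heights_p, coph_p = naive_hierarchical(X_probes, "cityblock", "complete")
        np.testing.assert_allclose(sorted(z_probes[:, 2]), sorted(heights_p), rtol=1e-10)
        np.testing.assert_allclose(_coph_matrix(z_probes, 8), coph_p, rtol=1e-10)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = _matrix(rng.uniform(0, 1, size=(12, 6)))
        z1, _, order1, _ = two_way_cluster(values)
        permuted = values[rng.permutation(values.columns)]
        z2, _, order2, _ = two_way_cluster(permuted)
        assert order1 == order2
        np.testing.assert_array_equal(z1, z2)


def _coph_matrix(z, n):
    from scipy.spatial.distance import squareform
    return squareform(cophenet(z))


class TestAssignEpigenotypes:
    def _planted(self, means, n_per=5, n_probes=40, noise=0.02, seed=0, normals_in=None):
        """Blocks with anti-correlated profiles at the given overall means."""
        rng = np.random.default_rng(seed)
        shapes = rng.uniform(-1, 1, size=(len(means), n_probes))
        cols, names, planted = [], [], []
        for b, mean in enumerate(means):
            profile = np.clip(mean + 0.08 * shapes[b], 0, 1)
            for j in range(n_per):
                cols.append(np.clip(profile + rng.normal(0, noise, n_probes), 0, 1))
                names.append(f"b{b}_s{j}")
                planted.append(b)
        values = pd.DataFrame(np.column_stack(cols), columns=names,
                              index=[f"g{i}" for i in range(n_probes)])
        return values, pd.Series(planted, index=names)

    def test_labels_follow_descending_means(self):
        values, planted = self._planted([0.55, 0.40, 0.25, 0.10])
        assignment = assign_epigenotypes(values, k=4)
        label_of_block = {b: assignment.labels[f"b{b}_s0"] for b in range(4)}
        assert [label_of_block[b] for b in range(4)] == ["HME", "IME", "LME", "NME"]
        means = assignment.cluster_means
        assert list(means.index) == ["HME", "IME", "LME", "NME"]
        assert means.is_monotonic_decreasing

    def test_normal_majority_check(self):
        values, _ = self._planted([0.55, 0.40, 0.25, 0.10])
        metadata = pd.DataFrame({"cohort": ["normal" if s.startswith("b3") else "sporadic_CRC"
                                            for s in values.columns]}, index=values.columns)
        assignment = assign_epigenotypes(values, metadata=metadata, k=4)
        assert all(assignment.labels[s] == "NME" for s in values.columns if s.startswith("b3"))

        # normals planted half in the top block -> inconsistency error
        bad = pd.DataFrame({"cohort": ["normal" if s.endswith(("s0", "s1"))
                                       and s.startswith(("b0", "b3")) else "sporadic_CRC"
                                       for s in values.columns]}, index=values.columns)
        with pytest.raises(EpigenotypeError, match="normal-sample"):
            assign_epigenotypes(values, metadata=bad, k=4)

    def test_determinism(self):
        values, _ = self._planted([0.55, 0.40, 0.25, 0.10], seed=5)
        a1 = assign_epigenotypes(values, k=4)
        a2 = assign_epigenotypes(values[list(values.columns[::-1])], k=4)
        pd.testing.assert_series_equal(a1.labels, a2.labels)
        np.testing.assert_array_equal(a1.sample_linkage, a2.sample_linkage)


class TestRecluster:
    def _fap_like(self, n_high=5, n_low=22, outlier=True, seed=0):
        rng = np.random.default_rng(seed)
        n_probes = 60
        shape = rng.uniform(-1, 1, n_probes)
        high = np.clip(0.45 + 0.15 * shape, 0, 1)
        low = np.clip(0.12 + 0.05 * shape[::-1], 0, 1)
        cols, names = [], []
        for j in range(n_high):
            cols.append(np.clip(high + rng.normal(0, 0.03, n_probes), 0, 1))
            names.append(f"hi_{j}")
        for j in range(n_low):
            cols.append(np.clip(low + rng.normal(0, 0.03, n_probes), 0, 1))
            names.append(f"lo_{j}")
        if outlier:
            cols.append(np.clip(1 - (high + low) / 2, 0, 1))
            names.append("weird")
        return pd.DataFrame(np.column_stack(cols), columns=names,
                            index=[f"g{i}" for i in range(n_probes)])

    def test_outlier_flagged_and_split_recovered(self):
        values = self._fap_like()
        assignment = recluster_subset(values, list(values.columns), k=2, min_cluster_size=2)
        assert assignment.outliers == ["weird"]
        assert sorted(assignment.labels.value_counts().to_dict().items()) == \
            [("IME", 5), ("NME", 22)]
        assert all(assignment.labels[s] == "IME" for s in values.columns if s.startswith("hi"))

    def test_min_cluster_size_one_disables_flagging(self):
        values = self._fap_like()
        assignment = recluster_subset(values, list(values.columns), k=2, min_cluster_size=1)
        assert assignment.outliers == []
        assert assignment.labels.size == 28

    def test_homogeneous_subset_still_labels_by_mean(self):
        values = self._fap_like(n_high=0, n_low=10, outlier=False)
        assignment = recluster_subset(values, list(values.columns), k=2, min_cluster_size=1)
        assert set(assignment.labels.unique()) == {"IME", "NME"}
        assert assignment.cluster_means["IME"] > assignment.cluster_means["NME"]


class TestEstimatorInterface:
    def test_fit_predict_and_params(self, scaled_cohort):
        from sklearn.base import clone

        X = scaled_cohort.beta.values.T  # samples x probes
        est = EpigenotypeClusterer(n_clusters=4, min_cluster_size=2)
        labels = est.fit_predict(X, metadata=scaled_cohort.metadata)
        assert len(labels) == X.shape[0]
        assert set(est.cluster_means_.index) == {"HME", "IME", "LME", "NME"}
        truth = scaled_cohort.truth.sample_labels
        keep = [i for i, s in enumerate(X.index)
                if truth[s] != "outlier" and labels[i] != "outlier"]
        ari = adjusted_rand_score(truth[X.index[keep]], labels[keep])
        assert ari >= 0.95
        assert clone(est).get_params()["n_clusters"] == 4

    def test_newick_export_round_trips_leaves(self):
        rng = np.random.default_rng(1)
        values = _matrix(rng.uniform(0, 1, size=(10, 5)))
        z, _, order, _ = two_way_cluster(values)
        newick = linkage_to_newick(z, order)
        assert newick.endswith(";")
        for leaf in order:
            assert leaf in newick
        from io import StringIO

        from Bio import Phylo
        tree = Phylo.read(StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(order)
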