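"""Filter cascade: concordance, CpG score, promoter selection, variance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epigenotyper.io import BetaMatrix, InputError
from epigenotyper.probe_filtering import (BetaVarianceFilter, FFPEConcordanceFilter,
                                          HighCpGSelector, concordant_probes, cpg_score,
                                          high_cpg_genes, select_promoter_probe,
                                          select_promoter_probes, variance_filter)


def _pair(frozen, ffpe, probes=None):
    probes = probes or [f"P{i}" for i in range(len(frozen))]
    return (pd.Series(frozen, index=probes, dtype=float),
            pd.Series(ffpe, index=probes, dtype=float))


class TestConcordance:
    def test_identical_vectors_retain_all(self):
        result = concordant_probes([_pair([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])], 0.1)
        assert result.intersection == {"P0", "P1", "P2"}

    def test_two_pair_intersection(self):
        # pair1 deltas {A: 0.05, B: 0.15}; pair2 deltas {A: 0.09, B: 0.00}
        p1 = _pair([0.50, 0.50], [0.55, 0.65], ["A", "B"])
        p2 = _pair([0.50, 0.50], [0.59, 0.50], ["A", "B"])
        result = concordant_probes([p1, p2], 0.1)
        assert result.per_pair[0] == {"A"}
        assert result.per_pair[1] == {"A", "B"}
        assert result.intersection == {"A"}

    def test_boundary_delta_is_excluded(self):
        # 0.1 - 0.0 is exactly the float 0.1: a delta at the threshold is out
        result = concordant_probes([_pair([0.0], [0.1])], 0.1)
        assert result.intersection == frozenset()

    def test_missing_value_is_non_concordant(self):
        result = concordant_probes([_pair([0.5, np.nan], [0.5, 0.5])], 0.1)
        assert result.intersection == {"P0"}

    def test_errors(self):
        with pytest.raises(InputError, match="at least one"):
            concordant_probes([], 0.1)
        with pytest.raises(InputError, match="universe"):
            concordant_probes([_pair([0.1], [0.1], ["A"]), _pair([0.1], [0.1], ["B"])], 0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_and_monotone(self, seed):
        """Per-pair sets match a set-comprehension oracle; intersection shrinks with pairs."""
        rng = np.random.default_rng(seed)
        probes = [f"P{i}" for i in range(rng.integers(2, 40))]
        pairs = [_pair(rng.uniform(0, 1, len(probes)), rng.uniform(0, 1, len(probes)), probes)
                 for _ in range(rng.integers(1, 5))]
        result = concordant_probes(pairs, 0.1)
        oracle_sets = [frozenset(p for p in probes if abs(fr[p] - ff[p]) < 0.1)
                       for fr, ff in pairs]
        assert result.per_pair == oracle_sets
        assert result.intersection == frozenset.intersection(*oracle_sets)
        prev = None
        for k in range(1, len(pairs) + 1):
            inter = concordant_probes(pairs[:k], 0.1).intersection
            assert prev is None or inter <= prev
            prev = inter


def _scan_oracle(seq: str) -> float:
    """Independent character-scan o/e CpG ratio."""
    seq = seq.upper()
    n_c = sum(ch == "C" for ch in seq)
    n_g = sum(ch == "G" for ch in seq)
    n_cpg = sum(seq[i] == "C" and seq[i + 1] == "G" for i in range(len(seq) - 1))
    length = sum(ch != "N" for ch in seq)
    return 0.0 if n_c * n_g == 0 else n_cpg / (n_c * n_g / length)


_RC = str.maketrans("ACGTN", "TGCAN")


class TestCpGScore:
    def test_alternating_cg_repeat(self):
        assert cpg_score("CG" * 250) == pytest.approx(2.0)

    def test_at_repeat_is_zero(self):
        assert cpg_score("AT" * 250) == 0.0

    def test_constructed_half_score(self):
        # 10 CpGs among 100 C and 100 G in 500 bp -> 10 / (100*100/500) = 0.5
        seq = "CGA" * 10 + "CA" * 90 + "GA" * 90 + "T" * 110
        assert len(seq) == 500
        assert cpg_score(seq) == pytest.approx(0.5)
        assert cpg_score(seq) > 0.48

    def test_errors(self):
        with pytest.raises(InputError):
            cpg_score("")
        with pytest.raises(InputError):
            cpg_score("ACGU" * 125)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=2, max_size=500))
    def test_matches_scan_oracle_and_reverse_complement(self, seq):
        if len(seq) - seq.count("N") < 2:
            return
        assert cpg_score(seq) == pytest.approx(_scan_oracle(seq), rel=1e-12)
        rc = seq.translate(_RC)[::-1]
        assert cpg_score(seq) == pytest.approx(cpg_score(rc), rel=1e-12)


class TestPromoterSelection:
    def test_nearest_and_single(self):
        probe = select_promoter_probe("G", {"a": 1300, "b": 1050}, 1000)
        assert probe.probe_id == "b" and probe.tss_distance == 50
        assert select_promoter_probe("G", {"only": 1500}, 1000).probe_id == "only"

    def test_tie_goes_to_smaller_coordinate(self):
        probe = select_promoter_probe("G", {"up": 900, "down": 1100}, 1000)
        assert probe.probe_id == "up"

    def test_no_candidates(self):
        with pytest.raises(InputError):
            select_promoter_probe("G", {}, 1000)


def _annotation(rows):
    frame = pd.DataFrame(rows, columns=["probe_id", "gene", "position",
                                        "tss_position", "cpg_score"])
    frame["chromosome"] = "chr1"
    frame["strand"] = "+"
    return frame.set_index("probe_id")


class TestHighCpG:
    def test_strict_threshold(self):
        ann = _annotation([("p1", "A", 1000, 1000, 0.50),
                           ("p2", "B", 2000, 2000, 0.48),
                           ("p3", "C", 3000, 3000, 0.47)])
        genes = high_cpg_genes(ann, 0.48)
        assert set(genes.index) == {"A"}

    def test_one_probe_per_gene(self):
        ann = _annotation([("p1", "A", 1300, 1000, 0.9),
                           ("p2", "A", 1050, 1000, 0.6),
                           ("p3", "B", 2000, 2000, 0.7)])
        genes = high_cpg_genes(ann, 0.48)
        assert genes.loc["A", "probe_id"] == "p2"  # nearest TSS, its score is used
        assert len(genes) == 2

    def test_missing_score_is_error(self):
        ann = _annotation([("p1", "A", 1000, 1000, np.nan)])
        with pytest.raises(InputError, match="lacking"):
            high_cpg_genes(ann, 0.48)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        ann = _annotation([(f"p{i}", f"G{i}", 1000 * i + 500, 1000 * i,
                            float(np.round(rng.uniform(0, 1.2), 3))) for i in range(n)])
        got = set(high_cpg_genes(ann, 0.48).index)
        expected = {g for g, s in zip(ann["gene"], ann["cpg_score"]) if s > 0.48}
        assert got == expected


class TestVarianceFilter:
    def test_hand_computed_sd(self):
        values = pd.DataFrame({"s1": [0.0, 0.3], "s2": [0.0, 0.3],
                               "s3": [1.0, 0.3], "s4": [1.0, 0.3]},
                              index=["var", "const"])
        kept = variance_filter(values, 0.10)
        assert kept == ["var"]
        assert values.loc["var"].std(ddof=1) == pytest.approx(np.sqrt(1 / 3))

    def test_boundary_sd_excluded(self):
        # SD exactly 0.10: values mean 0.5 +/- delta with delta = 0.1*sqrt(3)/2
        delta = 0.10 * np.sqrt(3) / 2
        row = [0.5 - delta, 0.5 - delta, 0.5 + delta, 0.5 + delta]
        values = pd.DataFrame([row], index=["edge"])
        assert values.loc["edge"].std(ddof=1) == pytest.approx(0.10)
        assert variance_filter(values, 0.10) == []

    def test_too_few_values(self):
        values = pd.DataFrame({"s1": [0.1], "s2": [np.nan]}, index=["p"])
        with pytest.raises(InputError, match="fewer than 2"):
            variance_filter(values, 0.10)


class TestCascadeProperties:
    def test_order_stability(self, scaled_cohort):
        """The cascade output probe set is invariant to input row order."""
        cohort = scaled_cohort
        shuffled = BetaMatrix(cohort.beta.values.sample(frac=1.0, random_state=4))
        for matrix in (cohort.beta, shuffled):
            genes = high_cpg_genes(cohort.annotation, 0.48)
            keep = matrix.values.loc[[p for p in matrix.values.index
                                      if p in set(genes["probe_id"])]]
            assert set(variance_filter(keep, 0.10)) == \
                set(variance_filter(cohort.beta.values, 0.10))

    def test_estimator_forms(self, scaled_cohort):
        """sklearn-shaped transformers mirror the functional results."""
        from sklearn.base import clone

        values = scaled_cohort.beta.values
        vf = BetaVarianceFilter(sd_threshold=0.10).fit(values)
        assert set(vf.selected_probes_) == set(variance_filter(values, 0.10))
        assert clone(vf).get_params() == {"sd_threshold": 0.10}
        sel = HighCpGSelector(score_threshold=0.48).fit(scaled_cohort.annotation)
        assert set(sel.genes_.index) == set(high_cpg_genes(scaled_cohort.annotation, 0.48).index)
        assert sel.transform(values).shape[0] == len(sel.selected_probes_)

    def test_concordance_estimator(self):
        probes = [f"P{i}" for i in range(30)]
        rng = np.random.default_rng(0)
        base = rng.uniform(0.1, 0.9, 30)
        pairs = [(pd.Series(base, index=probes), pd.Series(base, index=probes))]
        filt = FFPEConcordanceFilter(threshold=0.1).fit(pairs)
        matrix = pd.DataFrame(rng.uniform(0, 1, (30, 4)), index=probes)
        assert filt.transform(matrix).shape == (30, 4)
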