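import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainbench.deconvolution import InferenceResult
from strainbench.strain_matching import (
    classify_detection,
    collapse_duplicates,
    cumulative_abundance_correlation,
    detection_table,
    discretize_genotype,
    identify_lbp_strain,
    jaccard_matrix,
    jaccard_similarity,
    lbp_abundance_rmse,
    match_table,
)


def _genotype_frame(vectors: dict[str, list[int]]) -> pd.DataFrame:
    return pd.DataFrame({k: np.array(v, dtype=float) for k, v in vectors.items()}).T


def _result(genotypes: dict[str, list[float]], abundances: dict[str, dict[str, float]]):
    g = _genotype_frame(genotypes)
    ab = pd.DataFrame(abundances).T[list(g.index)]
    return InferenceResult(genotypes=g, abundances=ab)


class TestDiscretize:
    def test_threshold_with_tie_to_alternate(self):
        np.testing.assert_array_equal(
            discretize_genotype(np.array([0.9, 0.1, 0.5])), [1, 0, 1]
        )

    def test_all_zero_stays_zero(self):
        np.testing.assert_array_equal(discretize_genotype(np.zeros(4)), np.zeros(4))

    def test_binary_input_idempotent(self):
        g = np.array([0.0, 1.0, 1.0, 0.0])
        for threshold in (0.2, 0.5, 1.0):
            np.testing.assert_array_equal(discretize_genotype(g, threshold), g)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            discretize_genotype(np.array([1.2]))


class TestJaccard:
    def test_identical_genotypes(self):
        g = np.array([1, 0, 1, 1, 0])
        assert jaccard_similarity(g, g) == 1.0

    def test_disjoint_alternate_sets(self):
        assert jaccard_similarity(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_partial_overlap(self):
        # alt sets {1,2} vs {2,3}: intersection 1, union 3
        a = np.array([0, 1, 1, 0])
        b = np.array([0, 0, 1, 1])
        assert jaccard_similarity(a, b) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        assert jaccard_similarity(np.zeros(5), np.zeros(5)) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jaccard_similarity(np.zeros(3), np.zeros(4))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 2**10 - 1), st.integers(0, 2**10 - 1))
    def test_symmetry_and_identity(self, x, y):
        a = np.array([(x >> i) & 1 for i in range(10)])
        b = np.array([(y >> i) & 1 for i in range(10)])
        assert jaccard_similarity(a, b) == jaccard_similarity(b, a)
        assert (jaccard_similarity(a, b) == 1.0) == bool((a == b).all() or (a | b).sum() == 0)

    def test_jaccard_distance_triangle_inequality(self, rng):
        """1 - J is a metric: brute-force check on random genotype triples."""
        for _ in range(200):
            a, b, c = (rng.integers(0, 2, 6) for _ in range(3))
            dab = 1 - jaccard_similarity(a, b)
            dbc = 1 - jaccard_similarity(b, c)
            dac = 1 - jaccard_similarity(a, c)
            assert dac <= dab + dbc + 1e-12

    def test_matrix_agrees_with_pairwise(self, rng):
        a = rng.integers(0, 2, size=(4, 20))
        b = rng.integers(0, 2, size=(3, 20))
        mat = jaccard_matrix(a, b)
        for i, j in itertools.product(range(4), range(3)):
            assert mat[i, j] == pytest.approx(jaccard_similarity(a[i], b[j]))


class TestMatchTable:
    def test_exact_copies_match_once_at_threshold_one(self):
        truth = _genotype_frame({"A": [1, 0, 1], "B": [0, 1, 0], "C": [1, 1, 1]})
        counts = match_table(truth, truth.copy(), [1.0])
        assert (counts["n_matches"] == 1).all()

    def test_hand_computed_counts(self):
        # J(T1,I1)=1, J(T1,I2)=2/3, J(T2,*)=0 at threshold 0.6 -> T1:2, T2:0
        truth = _genotype_frame(
            {"T1": [0, 1, 1, 1, 0, 0, 0, 0, 0], "T2": [0, 0, 0, 0, 0, 0, 0, 1, 0]}
        )
        inferred = _genotype_frame(
            {
                "I1": [0, 1, 1, 1, 0, 0, 0, 0, 0],
                "I2": [0, 1, 1, 0, 0, 0, 0, 0, 0],
                "I3": [0, 0, 0, 0, 0, 0, 0, 0, 1],
            }
        )
        counts = match_table(truth, inferred, [0.6]).set_index("true_strain")
        assert counts.loc["T1", "n_matches"] == 2
        assert counts.loc["T2", "n_matches"] == 0

    def test_counts_monotone_in_threshold(self, rng):
        truth = pd.DataFrame(rng.integers(0, 2, size=(5, 40)).astype(float))
        inferred = pd.DataFrame(rng.integers(0, 2, size=(12, 40)).astype(float))
        counts = match_table(truth, inferred, [0.1, 0.3, 0.5, 0.7, 0.9])
        for _, grp in counts.groupby("true_strain"):
            ordered = grp.sort_values("threshold")["n_matches"].to_numpy()
            assert (np.diff(ordered) <= 0).all()


class TestCollapse:
    def test_identical_pair_merges_with_summed_abundance(self):
        res = _result(
            {"X": [1, 0, 1], "Y": [1, 0, 1], "Z": [0, 1, 0]},
            {"s1": {"X": 0.3, "Y": 0.2, "Z": 0.5}, "s2": {"X": 0.6, "Y": 0.4, "Z": 0.0}},
        )
        out = collapse_duplicates(res, 0.99)
        assert out.n_strains == 2
        assert out.abundances.loc["s1", "X"] == pytest.approx(0.5)
        assert out.abundances.loc["s2", "X"] == pytest.approx(1.0)

    def test_distinct_strains_untouched(self):
        res = _result(
            {"X": [1, 0, 0], "Y": [0, 0, 1]},
            {"s": {"X": 0.5, "Y": 0.5}},
        )
        out = collapse_duplicates(res, 0.99)
        assert out.n_strains == 2

    def test_triple_merge_keeps_most_abundant_survivor(self):
        res = _result(
            {"A": [1, 1, 0], "B": [1, 1, 0], "C": [1, 1, 0]},
            {"s": {"A": 0.3, "B": 0.5, "C": 0.2}},
        )
        out = collapse_duplicates(res, 0.99)
        assert out.strain_ids == ["B"]
        assert out.abundances.loc["s", "B"] == pytest.approx(1.0)

    def test_conserves_per_sample_totals(self, tiny_fit):
        out = collapse_duplicates(tiny_fit, 0.99)
        before = tiny_fit.abundances.sum(axis=1)
        after = out.abundances.sum(axis=1)
        assert np.allclose(before, after, atol=1e-9)
        assert out.n_strains <= tiny_fit.n_strains


class TestIdentifyLbp:
    def test_exact_copy_found_with_similarity_one(self):
        res = _result(
            {"X": [1, 0, 1, 0], "Y": [0, 1, 0, 0]},
            {"s": {"X": 0.7, "Y": 0.3}},
        )
        sid, similarity, _ = identify_lbp_strain(res, np.array([1, 0, 1, 0]))
        assert sid == "X"
        assert similarity == 1.0

    def test_disjoint_genotypes_score_zero(self):
        res = _result({"X": [1, 1, 0, 0]}, {"s": {"X": 1.0}})
        _, similarity, _ = identify_lbp_strain(res, np.array([0, 0, 1, 1]))
        assert similarity == 0.0

    def test_merging_reunites_split_spike_strain(self):
        lbp = np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 1])
        near = lbp.copy()
        res = _result(
            {"X": list(lbp), "Y": list(near), "Z": [0, 1, 0, 0, 1, 0, 0, 1, 0, 0]},
            {"s": {"X": 0.4, "Y": 0.35, "Z": 0.25}},
        )
        sid, similarity, merged = identify_lbp_strain(res, lbp, 0.95)
        assert similarity == 1.0
        assert merged.abundances.loc["s", sid] == pytest.approx(0.75)


class TestDetection:
    @pytest.mark.parametrize(
        "true_ab,inferred_ab,label",
        [
            (0.0, 0.05, "FP"),
            (0.0, 0.005, "TN"),
            (0.10, 0.04, "FN"),
            (0.50, 0.45, "TP"),
            (0.10, 0.12, "TP"),
            (0.0, 0.01, "TN"),
            (0.10, 0.07, "indeterminate"),
            (0.30, 0.05, "indeterminate"),
        ],
    )
    def test_rule_table(self, true_ab, inferred_ab, label):
        assert classify_detection(true_ab, inferred_ab).label == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_detection(-0.1, 0.5)
        with pytest.raises(ValueError):
            classify_detection(0.5, 1.5)

    def test_table_aligns_on_sample_id(self):
        truth = pd.Series({"a": 0.0, "b": 0.5})
        inferred = pd.Series({"b": 0.5, "a": 0.2})
        table = detection_table(truth, inferred)
        assert list(table["label"]) == ["FP", "TP"]


class TestAbundanceRmse:
    def test_zero_when_exact(self):
        truth = pd.Series({"a": 0.2, "b": 0.8})
        depths = pd.Series({"a": 5, "b": 30})
        out = lbp_abundance_rmse(truth, truth.copy(), depths)
        assert out == {5: 0.0, 30: 0.0}

    def test_constant_offset(self):
        truth = pd.Series({"a": 0.2, "b": 0.4, "c": 0.6})
        inferred = truth + 0.01
        depths = pd.Series({"a": 10, "b": 10, "c": 20})
        out = lbp_abundance_rmse(truth, inferred, depths)
        assert out[10] == pytest.approx(0.01)
        assert out[20] == pytest.approx(0.01)


class TestCumulativeCorrelation:
    def test_perfect_inference_gives_r_one(self):
        truth = _genotype_frame({"A": [1, 0, 1, 0], "B": [0, 1, 0, 1]})
        res = _result(
            {"A'": [1, 0, 1, 0], "B'": [0, 1, 0, 1]},
            {"s1": {"A'": 0.2, "B'": 0.8}, "s2": {"A'": 0.7, "B'": 0.3}},
        )
        cum = pd.Series({"A": 0.9, "B": 1.1})
        pairs, r = cumulative_abundance_correlation(truth, cum, res)
        assert len(pairs) == 2
        assert r == pytest.approx(1.0)

    def test_fewer_than_two_pairs_flagged_nan(self):
        truth = _genotype_frame({"A": [1, 0, 1, 0]})
        res = _result({"X": [1, 0, 1, 0]}, {"s": {"X": 1.0}})
        pairs, r = cumulative_abundance_correlation(truth, pd.Series({"A": 1.0}), res)
        assert len(pairs) == 1
        assert np.isnan(r)

    def test_excluded_strain_left_out(self):
        truth = _genotype_frame({"A": [1, 0, 1, 0], "sLBP": [0, 1, 0, 1]})
        res = _result(
            {"X": [1, 0, 1, 0], "Y": [0, 1, 0, 1]},
            {"s": {"X": 0.5, "Y": 0.5}},
        )
        pairs, _ = cumulative_abundance_correlation(
            truth, pd.Series({"A": 0.5, "sLBP": 0.5}), res, exclude_true=("sLBP",)
        )
        assert list(pairs["true_strain"]) == ["A"]
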