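import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from teaphenol.activity_ranking import (
    ActivityMatrix,
    average_linkage,
    correlation_distance,
    heatmap_matrix,
    raci,
    standard_scores,
)


def brute_force_upgma(D):
    """Independent UPGMA oracle: recompute every inter-cluster mean distance
    from the raw leaf matrix at each step (no incremental updates)."""
    n = D.shape[0]
    members = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(members) > 1:
        best = None
        for a in sorted(members):
            for b in sorted(members):
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in members[a] for j in members[b]])
                if best is None or (d, a, b) < best:
                    best = (d, a, b)
        d, a, b = best
        members[next_id] = members.pop(a) + members.pop(b)
        merges.append((a, b, d, len(members[next_id])))
        next_id += 1
    return merges


def random_distance_matrix(rng, n=6):
    a = rng.uniform(0.05, 2.0, size=(n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestStandardScores:
    def test_simple_example(self):
        assert np.allclose(standard_scores([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    @given(st.lists(st.integers(-10 ** 6, 10 ** 6), min_size=3, max_size=30,
                    unique=True))
    @settings(max_examples=100, deadline=None)
    def test_mean_zero_sd_one(self, xs):
        z = standard_scores([x / 1000.0 for x in xs])
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            standard_scores([5.0, 5.0, 5.0])


class TestRaci:
    def test_single_higher_better_metric_equals_z(self):
        m = ActivityMatrix(pd.DataFrame({"orac": [1.0, 2.0, 3.0]},
                                        index=list("abc")),
                           {"orac": "higher-better"})
        result = raci(m)
        assert np.allclose(result.raci.to_numpy(), [-1.0, 0.0, 1.0])

    def test_uniform_winner_has_largest_raci(self):
        values = pd.DataFrame({
            "id50": [1.0, 5.0, 9.0, 20.0],      # lower better: first wins
            "orac": [9.0, 4.0, 3.0, 1.0]},      # higher better: first wins
            index=list("wxyz"))
        m = ActivityMatrix(values, {"id50": "lower-better",
                                    "orac": "higher-better"})
        assert raci(m).ranking()[0] == "w"

    def test_reference_panel_ordering(self, activity_matrix, panel):
        """Oriented mean-z ordering matches the reported RACI ordering."""
        computed = raci(activity_matrix).ranking()
        reported = list(panel["raci_reported"].sort_values(ascending=False).index)
        assert computed == reported == ["TeaCEC", "TeaSNC", "TeaBNC",
                                        "TeaMTC", "TeaTWF", "TeaGNP"]

    def test_sum_is_zero_and_columns_standardized(self, activity_matrix):
        result = raci(activity_matrix)
        assert abs(result.raci.sum()) < 1e-12
        for col in result.z:
            assert abs(result.z[col].mean()) < 1e-12
            assert abs(result.z[col].std(ddof=1) - 1.0) < 1e-12

    def test_invariant_under_affine_metric_rescaling(self, activity_matrix):
        rescaled = activity_matrix.values.copy()
        rescaled["id50_dpph"] = rescaled["id50_dpph"] * 37.0 + 11.0
        m2 = ActivityMatrix(rescaled, activity_matrix.orientation)
        assert np.allclose(raci(m2).raci.to_numpy(),
                           raci(activity_matrix).raci.to_numpy())

    def test_constant_metric_rejected(self):
        m_values = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        m = ActivityMatrix(m_values, {"a": "higher-better", "b": "higher-better"})
        with pytest.raises(ValueError):
            raci(m)


class TestCorrelationDistance:
    def test_identical_rows_distance_zero(self):
        d = correlation_distance([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_distance_two(self):
        d = correlation_distance([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_half_correlation(self):
        d = correlation_distance([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]])
        assert d[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError):
            correlation_distance([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])


class TestAverageLinkage:
    def test_identical_profiles_merge_at_zero(self):
        D = np.zeros((2, 2))
        tree = average_linkage(D)
        assert tree.merges[0][2] == 0.0

    def test_three_leaf_hand_example(self):
        D = np.array([[0.0, 1.0, 4.0],
                      [1.0, 0.0, 4.0],
                      [4.0, 4.0, 0.0]])
        tree = average_linkage(D)
        (a, b, h1, _), (_, _, h2, _) = tree.merges
        assert {a, b} == {0, 1} and h1 == 1.0 and h2 == 4.0

    def test_structure_invariants(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            D = random_distance_matrix(rng, n=7)
            tree = average_linkage(D)
            assert len(tree.merges) == 6
            assert (np.diff(tree.heights) >= -1e-12).all()
            assert sorted(tree.leaf_order()) == list(range(7))

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            D = random_distance_matrix(rng)
            ours = average_linkage(D).merges
            oracle = brute_force_upgma(D)
            for (a1, b1, h1, s1), (a2, b2, h2, s2) in zip(ours, oracle):
                assert {a1, b1} == {a2, b2} and s1 == s2
                assert h1 == pytest.approx(h2, rel=1e-10)

    def test_agrees_with_scipy_heights(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            D = random_distance_matrix(rng)
            ours = average_linkage(D).heights
            scipy_heights = linkage(squareform(D), method="average")[:, 2]
            assert np.allclose(np.sort(ours), np.sort(scipy_heights))

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            average_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_newick_output_parses(self):
        import dendropy

        D = random_distance_matrix(np.random.default_rng(3), n=5)
        text = average_linkage(D).to_newick(list("abcde"))
        tree = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == list("abcde")


class TestHeatmapMatrix:
    def test_rows_scaled_to_unit_sd(self, activity_matrix):
        scaled, _, _ = heatmap_matrix(activity_matrix)
        sds = scaled.std(axis=1, ddof=1)
        assert np.allclose(sds.to_numpy(), 1.0)

    def test_two_block_structure_recovered(self):
        rng = np.random.default_rng(0)
        block_a = np.outer(np.ones(3), [1, 2, 3, 4]) + rng.normal(0, 0.05, (3, 4))
        block_b = np.outer(np.ones(3), [4, 3, 2, 1]) + rng.normal(0, 0.05, (3, 4))
        values = pd.DataFrame(np.vstack([block_a, block_b]),
                              index=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)])
        m = ActivityMatrix(values, {c: "higher-better" for c in values.columns})
        _, row_order, _ = heatmap_matrix(m)
        labels = "".join(s[0] for s in row_order)
        assert labels in ("aaabbb", "bbbaaa")
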