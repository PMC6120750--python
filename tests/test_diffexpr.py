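import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernaflow.diffexpr import (
    DEConfig,
    bh_fdr,
    differential_expression,
    hierarchical_order,
    quantile_normalize,
    relative_expression_ddct,
)
from cernaflow.errors import ConfigurationError
from cernaflow.model import ExpressionMatrix

GROUPS4 = {"c1": "case", "c2": "case", "k1": "control", "k2": "control"}


def matrix_from(values, columns, groups, index=None):
    df = pd.DataFrame(values, columns=columns,
                      index=index or [f"t{i}" for i in range(len(values))])
    return ExpressionMatrix(values=df, group_of=groups)


class TestQuantileNormalize:
    def test_two_column_order_statistic_means(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        expected = [2.5, 3.5, 4.5]
        assert out["a"].tolist() == expected
        assert out["b"].tolist() == expected

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(df)
        assert np.allclose(out, df)

    def test_tied_entries_share_mean_of_tied_rank_targets(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [3.0, 4.0, 5.0]})
        out = quantile_normalize(df)
        # targets: rank1 (1+3)/2=2, rank2 (1+4)/2=2.5, rank3 (2+5)/2=3.5
        assert out["a"].tolist() == [2.25, 2.25, 3.5]
        assert out["b"].tolist() == [2.0, 2.5, 3.5]

    def test_single_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_total_sum_preserved(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.uniform(0, 100, (30, 5)))
        out = quantile_normalize(df)
        assert np.isclose(out.to_numpy().sum(), df.to_numpy().sum(), rtol=1e-6)


class TestDifferentialExpression:
    def test_fold_change_arithmetic_and_direction(self):
        m = matrix_from([[8.0, 8.1, 2.0, 2.1],
                         [1.0, 1.05, 3.9, 4.0]],
                        ["c1", "c2", "k1", "k2"], GROUPS4)
        rec_up, rec_down = differential_expression(m)
        assert rec_up.fold_change == pytest.approx(
            rec_up.mean_case / rec_up.mean_control)
        assert rec_up.fold_change == pytest.approx(2 ** rec_up.log2fc, rel=1e-9)
        assert rec_up.direction == "up"
        assert rec_down.direction == "down"

    def test_fold_change_exactly_two_fails_strict_filter(self):
        # zero within-group variance with unequal means: degenerate tiny p
        m = matrix_from([[8.0, 8.0, 4.0, 4.0]], ["c1", "c2", "k1", "k2"],
                        GROUPS4)
        (rec,) = differential_expression(m)
        assert rec.fold_change == 2.0
        assert rec.degenerate and rec.p_value < 0.05
        assert not rec.passes_filter  # strict "> 2"

    def test_zero_variance_equal_means_p_one(self):
        m = matrix_from([[5.0, 5.0, 5.0, 5.0]], ["c1", "c2", "k1", "k2"],
                        GROUPS4)
        (rec,) = differential_expression(m)
        assert rec.p_value == 1.0 and not rec.degenerate

    def test_small_group_rejected(self):
        m = matrix_from([[1.0, 2.0, 3.0]], ["c1", "k1", "k2"],
                        {"c1": "case", "k1": "control", "k2": "control"})
        with pytest.raises(ConfigurationError):
            differential_expression(m)

    def test_label_swap_negates_log2fc_preserves_p(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(10, 1000, (20, 4))
        m = matrix_from(values, ["c1", "c2", "k1", "k2"], GROUPS4)
        swapped = ExpressionMatrix(
            values=m.values,
            group_of={"c1": "control", "c2": "control",
                      "k1": "case", "k2": "case"})
        for a, b in zip(differential_expression(m),
                        differential_expression(swapped)):
            assert a.log2fc == pytest.approx(-b.log2fc, abs=1e-12)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(10, 1000, (15, 4))
        m1 = matrix_from(values, ["c1", "c2", "k1", "k2"], GROUPS4)
        m2 = matrix_from(values * 7.5, ["c1", "c2", "k1", "k2"], GROUPS4)
        for a, b in zip(differential_expression(m1),
                        differential_expression(m2)):
            assert a.log2fc == pytest.approx(b.log2fc, abs=1e-9)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-9)


class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        adjusted = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=40))
    def test_monotone_bounded(self, pvals):
        p = np.array(pvals)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0 + 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


def _naive_average_linkage(dist):
    """Brute-force agglomeration in scipy linkage-matrix form."""
    n = dist.shape[0]
    active = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    z = []
    next_id = n
    while len(active) > 1:
        (i, j), best = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        members = active[i] + active[j]
        z.append([i, j, best, len(members)])
        del active[i], active[j]
        d = {k: v for k, v in d.items() if i not in k and j not in k}
        for k, mem in active.items():
            pair_dists = [dist[a, b] for a in members for b in mem]
            d[(min(k, next_id), max(k, next_id))] = float(np.mean(pair_dists))
        active[next_id] = members
        next_id += 1
    return np.array(z)


class TestHierarchicalOrder:
    def test_identical_rows_merge_first(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0],
                           [2.0, 4.0, 6.0, 8.0],
                           [4.0, 3.0, 2.0, 1.0]],
                          index=["a", "b", "c"])
        leaves, z = hierarchical_order(df)
        # rows a and b are perfectly correlated (distance 0): adjacent leaves
        ia, ib = leaves.index("a"), leaves.index("b")
        assert abs(ia - ib) == 1
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(8, 6)),
                          index=[f"t{i}" for i in range(8)])
        assert hierarchical_order(df)[0] == hierarchical_order(df)[0]

    def test_matches_bruteforce_average_linkage(self):
        from scipy.cluster.hierarchy import leaves_list
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(5, 10)),
                          index=[f"t{i}" for i in range(5)])
        leaves, z = hierarchical_order(df)
        arr = df.sort_index().to_numpy()
        dist = 1.0 - np.corrcoef(arr)
        np.fill_diagonal(dist, 0.0)
        z_ref = _naive_average_linkage(dist)
        ref_leaves = [df.sort_index().index[i] for i in leaves_list(z_ref)]
        assert leaves == ref_leaves

    def test_constant_row_distance_one_with_warning(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0, 1.0],
                           [1.0, 2.0, 3.0, 4.0],
                           [2.0, 4.0, 6.0, 8.0]],
                          index=["const", "x", "y"])
        with pytest.warns(UserWarning, match="constant"):
            leaves, _ = hierarchical_order(df)
        assert set(leaves) == {"const", "x", "y"}


@pytest.mark.parametrize("cts,expected", [
    ((20.0, 20.0, 20.0, 20.0), 1.0),   # ddCt = 0
    ((18.0, 20.0, 20.0, 20.0), 4.0),   # ddCt = -2
    ((21.0, 20.0, 20.0, 20.0), 0.5),   # ddCt = 1
])
def test_relative_expression_ddct(cts, expected):
    assert relative_expression_ddct(*cts) == pytest.approx(expected)
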