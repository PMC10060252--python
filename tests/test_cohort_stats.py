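import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ircohort import cohort_stats as cs


def matrix_from(values, groups, mode="iri"):
    df = pd.DataFrame(
        values, index=[f"g{i}" for i in range(len(values))]
    )
    df.columns = list(groups)
    return cs.CohortMatrix(df, groups, mode=mode)


def two_group_matrix(rng, n_genes=20, n_case=3, n_ctrl=2):
    cols = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_ctrl)]
    groups = {c: ("case" if c.startswith("c") else "control") for c in cols}
    df = pd.DataFrame(
        rng.normal(size=(n_genes, len(cols))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
    )
    return cs.CohortMatrix(df, groups)


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------


class TestZScore:
    def test_rows_standardized(self, rng):
        m = two_group_matrix(rng)
        z = cs.zscore(m)
        np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_zero_variance_rows_dropped_and_listed(self, rng):
        m = two_group_matrix(rng, n_genes=5)
        m.values.loc["g2"] = 7.0
        z = cs.zscore(m)
        assert z.dropped == ["g2"]
        assert "g2" not in z.values.index

    def test_idempotent(self, rng):
        m = two_group_matrix(rng)
        z1 = cs.zscore(m)
        m2 = cs.CohortMatrix(z1.values, m.groups)
        z2 = cs.zscore(m2)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-10)


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------


class TestHistogram:
    def test_constant_sample_summary(self, rng):
        m = two_group_matrix(rng, n_genes=10)
        m.values["c0"] = -6.0
        dens, edges, summary = cs.log2_iri_histogram(m)
        assert summary.loc["c0", "mean"] == pytest.approx(-6.0)
        assert summary.loc["c0", "sd"] == pytest.approx(0.0)

    def test_densities_integrate_to_one(self, rng):
        m = two_group_matrix(rng, n_genes=500)
        dens, edges, _ = cs.log2_iri_histogram(m, bins=40)
        widths = np.diff(edges)
        for s in m.samples:
            assert (dens[s] * widths).sum() == pytest.approx(1.0)

    def test_identical_samples_identical_densities(self, rng):
        m = two_group_matrix(rng, n_genes=100)
        m.values["k0"] = m.values["c0"]
        dens, _, _ = cs.log2_iri_histogram(m)
        np.testing.assert_array_equal(dens["k0"], dens["c0"])

    def test_configured_mean_recovered(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(-6.0, 0.8, size=(4000, 4))
        m = matrix_from(vals, {"a": "case", "b": "case", "c": "control", "d": "control"})
        _, _, summary = cs.log2_iri_histogram(m)
        assert summary["mean"].mean() == pytest.approx(-6.0, abs=0.05)

    def test_degenerate_errors(self):
        m = matrix_from(np.full((3, 2), 1.0), {"a": "case", "b": "control"})
        with pytest.raises(ValueError):
            cs.log2_iri_histogram(m)


# ---------------------------------------------------------------------------
# pairwise correlation
# ---------------------------------------------------------------------------


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


class TestPairwiseCorrelation:
    def test_duplicate_samples(self, rng):
        m = two_group_matrix(rng)
        m.values["k0"] = m.values["c0"]
        corr = cs.pairwise_sample_correlation(m)
        assert corr.loc["c0", "k0"] == pytest.approx(1.0)

    def test_negation(self, rng):
        m = two_group_matrix(rng)
        m.values["k0"] = -m.values["c0"]
        corr = cs.pairwise_sample_correlation(m)
        assert corr.loc["c0", "k0"] == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        vals = np.array(
            [[1.0, 2.0, 0.5], [3.0, -1.0, 2.0], [0.0, 4.0, 1.0], [2.0, 2.0, -3.0]]
        )
        m = matrix_from(vals, {"a": "case", "b": "case", "c": "control"})
        corr = cs.pairwise_sample_correlation(m)
        for i, j in itertools.combinations(range(3), 2):
            expected = pearson_oracle(vals[:, i].tolist(), vals[:, j].tolist())
            assert corr.iloc[i, j] == pytest.approx(expected)
            assert corr.iloc[j, i] == pytest.approx(expected)

    def test_constant_sample_nan(self, rng):
        m = two_group_matrix(rng)
        m.values["k1"] = 5.0
        corr = cs.pairwise_sample_correlation(m)
        assert corr.loc["k1", "c0"] != corr.loc["k1", "c0"]  # NaN
        assert corr.loc["k1", "k1"] == 1.0

    def test_positive_semidefinite(self, rng):
        m = two_group_matrix(rng, n_genes=50, n_case=6, n_ctrl=4)
        corr = cs.pairwise_sample_correlation(m)
        eig = np.linalg.eigvalsh(corr.to_numpy())
        assert eig.min() > -1e-10


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


def naive_average_linkage_heights(points):
    """O(n^3) agglomerative average linkage; returns sorted merge heights."""
    points = [np.asarray(p, dtype=float) for p in points]
    clusters = {i: [i] for i in range(len(points))}
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [
                    np.linalg.norm(points[i] - points[j])
                    for i in clusters[a]
                    for j in clusters[b]
                ]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return sorted(heights)


class TestHierarchicalCluster:
    def test_close_pair_merges_first(self):
        df = pd.DataFrame(
            {"a": [0.0, 0.0], "b": [1.0, 0.0], "c": [10.0, 0.0]}
        )
        z, labels = cs.hierarchical_cluster(df, axis="samples")
        assert {int(z[0, 0]), int(z[0, 1])} == {
            labels.index("a"),
            labels.index("b"),
        }

    def test_duplicates_merge_at_zero(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [5.0, 5.0]})
        z, _ = cs.hierarchical_cluster(df, axis="samples")
        assert z[0, 2] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(4, 6))  # 6 samples in 4-gene space
        df = pd.DataFrame(data, columns=[f"s{i}" for i in range(6)])
        z, _ = cs.hierarchical_cluster(df, axis="samples")
        expected = naive_average_linkage_heights(list(data.T))
        np.testing.assert_allclose(sorted(z[:, 2]), expected, atol=1e-10)

    def test_gene_axis(self, rng):
        m = two_group_matrix(rng, n_genes=5)
        z, labels = cs.hierarchical_cluster(m.values, axis="genes")
        assert labels == list(m.values.index)
        assert z.shape == (4, 4)

    def test_newick_roundtrip_structure(self):
        df = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [10.0]})
        z, labels = cs.hierarchical_cluster(df, axis="samples")
        nwk = cs.linkage_to_newick(z, labels)
        assert nwk.endswith(";") and nwk.count("(") == 2
        assert all(lbl in nwk for lbl in "abc")


# ---------------------------------------------------------------------------
# exact Mann-Whitney
# ---------------------------------------------------------------------------


def mw_brute_force(x, y):
    """Enumerate every group assignment of the pooled values directly."""
    pooled = list(x) + list(y)
    ranks = sps.rankdata(pooled)
    obs = ranks[: len(x)].sum()
    null = [
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), len(x))
    ]
    lo = sum(t <= obs + 1e-9 for t in null) / len(null)
    hi = sum(t >= obs - 1e-9 for t in null) / len(null)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitneyExact:
    def test_complete_separation_16v4(self):
        case = list(range(16))
        ctrl = [100, 101, 102, 103]
        p = cs.mann_whitney_exact(case, ctrl)
        assert p == pytest.approx(2 / math.comb(20, 4))
        assert p == pytest.approx(0.000413, abs=2e-6)

    def test_identical_multisets(self):
        assert cs.mann_whitney_exact([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_all_identical(self):
        assert cs.mann_whitney_exact([5, 5, 5], [5, 5]) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_3v2(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=3), rng.normal(size=2)
        assert cs.mann_whitney_exact(x, y) == pytest.approx(mw_brute_force(x, y))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, size=4).astype(float)
        y = rng.integers(0, 3, size=3).astype(float)
        if np.unique(np.concatenate([x, y])).size == 1:
            pytest.skip("degenerate draw")
        assert cs.mann_whitney_exact(x, y) == pytest.approx(mw_brute_force(x, y))

    def test_exact_close_to_asymptotic_at_15v15(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.6, 1, 15)
        y = rng.normal(0, 1, 15)
        exact = cs.mann_whitney_exact(x, y)  # falls back? comb(30,15) too big
        asym = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert exact == pytest.approx(asym, abs=0.01)

    def test_matrix_version_matches_scalar(self, rng):
        vals = rng.normal(size=(8, 9))
        mask = np.array([True] * 5 + [False] * 4)
        ps = cs.mann_whitney_exact_matrix(vals, mask)
        for row, p in zip(vals, ps):
            assert p == pytest.approx(
                cs.mann_whitney_exact(row[mask], row[~mask])
            )

    def test_group_mean_test_complete_separation(self):
        cols = [f"c{i}" for i in range(16)] + [f"k{i}" for i in range(4)]
        groups = {c: ("case" if c.startswith("c") else "control") for c in cols}
        vals = np.tile(
            np.concatenate([np.arange(16.0), [50, 51, 52, 53]]), (3, 1)
        )
        m = matrix_from(vals, groups)
        res = cs.group_mean_test(m)
        assert res["p"] == pytest.approx(2 / math.comb(20, 4))
        assert res["n_case"] == 16 and res["n_control"] == 4


# ---------------------------------------------------------------------------
# fold changes and coupling
# ---------------------------------------------------------------------------


class TestFoldChange:
    def test_ratio_of_group_means(self):
        groups = {"a": "case", "b": "case", "c": "control"}
        # iri mode: values are log2, linearized before averaging
        vals = np.log2(np.array([[2.0, 6.0, 2.0], [1.0, 1.0, 4.0]]))
        m = matrix_from(vals, groups)
        fc = cs.fold_change_table(m)
        assert fc.loc["g0", "fold_change"] == pytest.approx(4.0 / 2.0)
        assert fc.loc["g1", "fold_change"] == pytest.approx(1.0 / 4.0)

    def test_expression_mode_linear(self):
        groups = {"a": "case", "b": "control"}
        m = matrix_from(np.array([[10.0, 5.0]]), groups, mode="expression")
        fc = cs.fold_change_table(m)
        assert fc.loc["g0", "fold_change"] == pytest.approx(2.0)

    def test_zero_control_dropped(self):
        groups = {"a": "case", "b": "control"}
        m = matrix_from(np.array([[10.0, 0.0], [4.0, 2.0]]), groups, mode="expression")
        fc = cs.fold_change_table(m)
        assert list(fc.index) == ["g1"]


class TestCoupling:
    def _fc(self, log2_vals):
        return pd.DataFrame(
            {
                "fold_change": np.exp2(log2_vals),
                "log2_fc": log2_vals,
            },
            index=[f"g{i}" for i in range(len(log2_vals))],
        )

    def test_exact_anti_linearity(self, rng):
        iri = rng.normal(size=50)
        res = cs.fold_change_coupling(self._fc(iri), self._fc(-iri))
        assert res.r == pytest.approx(-1.0)

    def test_null_correlation_small(self):
        rng = np.random.default_rng(123)
        res = cs.fold_change_coupling(
            self._fc(rng.normal(size=1000)), self._fc(rng.normal(size=1000))
        )
        assert abs(res.r) < 0.1

    def test_gene_order_invariance(self, rng):
        iri = self._fc(rng.normal(size=40))
        expr = self._fc(rng.normal(size=40))
        r1 = cs.fold_change_coupling(iri, expr).r
        perm = rng.permutation(40)
        r2 = cs.fold_change_coupling(iri.iloc[perm], expr.iloc[perm]).r
        assert r1 == pytest.approx(r2)

    def test_ten_equal_bins_remainder_leftmost(self, rng):
        res = cs.fold_change_coupling(
            self._fc(rng.normal(size=103)), self._fc(rng.normal(size=103))
        )
        assert list(res.bins["n"]) == [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]
        # bins ordered by increasing IRI fold change
        assert res.bins["mean_iri_log2_fc"].is_monotonic_increasing

    def test_configured_correlation_recovered(self):
        rng = np.random.default_rng(5)
        rho = -0.34
        cov = [[1.0, rho], [rho, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=7645)
        res = cs.fold_change_coupling(self._fc(xy[:, 0]), self._fc(xy[:, 1]))
        assert res.r == pytest.approx(rho, abs=0.03)
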