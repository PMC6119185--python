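"""Co-expression network construction, TOM, module detection, export."""

import numpy as np
import pandas as pd
import pytest

import sennet
from sennet.coexpression import GREY
from sennet.dataset import ValidationError


def _dataset(values: np.ndarray) -> sennet.ExpressionDataset:
    n_genes, n_samples = values.shape
    assert n_samples % 2 == 0
    samples = pd.DataFrame(
        {
            "time": np.repeat(np.arange(n_samples // 2), 2),
            "replicate": np.tile([0, 1], n_samples // 2),
        },
        index=pd.Index([f"S{i}" for i in range(n_samples)], name="sample"),
    )
    return sennet.ExpressionDataset(
        values=pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)], columns=samples.index),
        samples=samples,
    )


class TestSimilarity:
    def test_duplicated_gene_has_unit_similarity(self):
        base = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
        s, genes = sennet.correlation_similarity(_dataset(np.vstack([base, base, base[::-1]])))
        assert s[0, 1] == pytest.approx(1.0)

    def test_exact_negation_unsigned_vs_signed(self):
        base = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
        data = _dataset(np.vstack([base, -base]))
        s_u, _ = sennet.correlation_similarity(data, mode="unsigned")
        s_s, _ = sennet.correlation_similarity(data, mode="signed")
        assert s_u[0, 1] == pytest.approx(1.0)
        assert s_s[0, 1] == pytest.approx(0.0)

    def test_three_gene_matrix_matches_textbook_pearson(self):
        x = np.array(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
             [2.0, 1.0, 4.0, 3.0, 6.0, 5.0],
             [1.0, 1.0, 2.0, 2.0, 3.0, 4.0]]
        )
        s, _ = sennet.correlation_similarity(_dataset(x))
        for i in range(3):
            for j in range(3):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                r = np.dot(xi, xj) / np.sqrt(np.dot(xi, xi) * np.dot(xj, xj))
                assert s[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_constant_gene_excluded_with_warning(self):
        base = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
        data = _dataset(np.vstack([base, np.full(6, 2.0)]))
        with pytest.warns(UserWarning, match="constant"):
            s, genes = sennet.correlation_similarity(data)
        assert genes == ["g0"]


class TestScaleFreeFit:
    def test_perfect_power_law_bins_give_unit_fit(self):
        # counts per connectivity value fall exactly on a log-log line
        ks, reps = [1.0, 10.0, 100.0], [1000, 100, 10]
        k = np.concatenate([np.full(r, kk) for kk, r in zip(ks, reps)])
        r2 = sennet.scale_free_fit(k, n_bins=200)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_regular_graph_is_degenerate(self):
        with pytest.raises(ValidationError, match="degenerate"):
            sennet.scale_free_fit(np.full(50, 7.0))

    def test_matches_independent_binned_regression(self):
        rng = np.random.default_rng(0)
        k = rng.pareto(2.0, size=500) + 1
        got = sennet.scale_free_fit(k, n_bins=10)
        # independent oracle: same binning recipe coded from scratch
        lo, hi = k.min(), k.max()
        width = (hi - lo) / 10
        pts = []
        for b in range(10):
            sel = (k >= lo + b * width) & (k < lo + (b + 1) * width) if b < 9 else (
                k >= lo + 9 * width
            )
            if sel.sum():
                pts.append((np.log10(k[sel].mean()), np.log10(sel.sum())))
        X = np.array([p[0] for p in pts])
        Y = np.array([p[1] for p in pts])
        slope = np.cov(X, Y, bias=True)[0, 1] / np.var(X)
        resid = Y - (Y.mean() + slope * (X - X.mean()))
        r2 = 1 - resid @ resid / ((Y - Y.mean()) @ (Y - Y.mean()))
        expected = r2 * np.sign(-slope)
        assert got == pytest.approx(expected, abs=1e-10)


class TestSoftThreshold:
    def test_smallest_qualifying_power_wins(self, default_bundle):
        _, expr, *_ = default_bundle
        s, _ = sennet.correlation_similarity(expr)
        beta, table = sennet.pick_soft_threshold(s, r2_goal=0.6)
        qualifying = table[table["signed_r2"] >= 0.6]["power"]
        assert beta == qualifying.min()

    def test_zero_goal_picks_first_candidate(self, default_bundle):
        _, expr, *_ = default_bundle
        s, _ = sennet.correlation_similarity(expr)
        beta, _ = sennet.pick_soft_threshold(s, candidate_powers=[4, 6, 8], r2_goal=-2.0)
        assert beta == 4

    def test_selection_is_reproducible(self, default_bundle, default_network):
        _, expr, *_ = default_bundle
        s, _ = sennet.correlation_similarity(expr)
        beta, _ = sennet.pick_soft_threshold(s)
        assert beta == default_network.power

    def test_adjacency_monotone_in_power(self, default_bundle):
        _, expr, *_ = default_bundle
        s, _ = sennet.correlation_similarity(expr)
        sub = s[:50, :50]
        assert np.all(sub**7 <= sub**6 + 1e-15)


def _naive_tom(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return tom


class TestTOM:
    def test_three_node_path_hand_values(self):
        a = np.array([[0, 0.5, 0.0], [0.5, 0, 0.5], [0.0, 0.5, 0]])
        tom = sennet.compute_tom(a)
        assert tom[0, 2] == pytest.approx(0.25 / 1.5, abs=1e-12)
        assert tom[0, 1] == pytest.approx(0.5 / 1.0, abs=1e-12)

    def test_zero_adjacency_gives_zero_overlap(self):
        tom = sennet.compute_tom(np.zeros((4, 4)))
        assert np.all(tom[~np.eye(4, dtype=bool)] == 0)
        assert np.all(np.diag(tom) == 1)

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValidationError):
            sennet.compute_tom(a)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(50, 50))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        np.testing.assert_allclose(sennet.compute_tom(a), _naive_tom(a), atol=1e-10)


class TestDetectModules:
    def _block_tom(self, sizes, within=0.9, between=0.05):
        n = sum(sizes)
        tom = np.full((n, n), between)
        pos = 0
        for s in sizes:
            tom[pos : pos + s, pos : pos + s] = within
            pos += s
        np.fill_diagonal(tom, 1.0)
        return tom

    def test_two_perfect_blocks_recovered(self):
        tom = self._block_tom([5, 5])
        part = sennet.detect_modules(tom, [f"g{i}" for i in range(10)], min_module_size=3)
        labs = part.labels
        assert labs.nunique() == 2 and GREY not in set(labs)
        assert labs.iloc[:5].nunique() == 1 and labs.iloc[5:].nunique() == 1

    def test_all_grey_when_min_size_exceeds_clusters(self):
        tom = self._block_tom([5, 5])
        part = sennet.detect_modules(tom, [f"g{i}" for i in range(10)], min_module_size=6)
        assert set(part.labels) == {GREY}

    def test_minimum_module_size_boundary(self):
        # a 99-gene cluster is grey at min size 100; a 100-gene cluster is not
        tom = self._block_tom([99, 100])
        part = sennet.detect_modules(tom, [f"g{i}" for i in range(199)], min_module_size=100)
        assert set(part.labels.iloc[:99]) == {GREY}
        assert GREY not in set(part.labels.iloc[99:])

    def test_labels_ranked_by_size(self):
        tom = self._block_tom([4, 8])
        part = sennet.detect_modules(tom, [f"g{i}" for i in range(12)], min_module_size=3)
        assert part.labels.iloc[4] == "turquoise"  # largest block first color
        assert part.labels.iloc[0] == "blue"

    def test_planted_module_recovery_on_default_bundle(self, default_bundle, default_network):
        from sklearn.metrics import adjusted_rand_score

        *_, truth = default_bundle
        net = default_network
        part = sennet.detect_modules(net.tom, net.gene_ids, min_module_size=30)
        detected = part.non_grey()
        planted = [truth.module_of[g] for g in detected.index]
        assert adjusted_rand_score(planted, list(detected)) >= 0.8


class TestEigengene:
    def test_identical_genes_give_shared_profile(self):
        base = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
        data = _dataset(np.vstack([base, base, base]))
        part = sennet.ModulePartition(
            labels=pd.Series("turquoise", index=data.values.index), min_module_size=2
        )
        eig, varexp = sennet.module_eigengene(data, part)
        z = (base - base.mean()) / base.std()
        expected = z / np.linalg.norm(z)
        np.testing.assert_allclose(eig["turquoise"], expected, atol=1e-10)
        assert varexp["turquoise"] == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 6))
        data = _dataset(x)
        part = sennet.ModulePartition(
            labels=pd.Series("blue", index=data.values.index), min_module_size=2
        )
        eig, varexp = sennet.module_eigengene(data, part)
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        _, s, vt = np.linalg.svd(z)
        oracle = vt[0] * np.sign(np.corrcoef(vt[0], x.mean(0))[0, 1])
        np.testing.assert_allclose(eig["blue"], oracle, atol=1e-10)
        assert 0 <= varexp["blue"] <= 1


class TestExport:
    def test_threshold_is_inclusive(self):
        w = np.eye(4)
        w[0, 1] = w[1, 0] = 0.74
        w[0, 2] = w[2, 0] = 0.75
        w[1, 2] = w[2, 1] = 0.76
        edges = sennet.export_network(w, list("abcd"), threshold=0.75)
        assert len(edges) == 2 and edges["weight"].min() == 0.75

    def test_zero_threshold_gives_complete_graph(self):
        w = np.random.default_rng(0).uniform(0, 1, (6, 6))
        w = (w + w.T) / 2
        assert len(sennet.export_network(w, list("abcdef"), threshold=0.0)) == 15

    def test_threshold_outside_unit_interval_errors(self):
        with pytest.raises(ValidationError):
            sennet.export_network(np.eye(3), list("abc"), threshold=1.01)
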