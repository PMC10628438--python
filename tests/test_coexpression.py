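import math

import numpy as np
import pandas as pd
import pytest

from scgrnet import coexpression as cx


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def oracle_bicor(x, y):
    """Direct evaluation of the biweight midcorrelation formula."""
    def transform(v):
        v = np.asarray(v, float)
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w
    xt, yt = transform(x), transform(y)
    return float(xt @ yt) / math.sqrt(float(xt @ xt) * float(yt @ yt))


def oracle_tom(a):
    """Triple-loop topological overlap."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def oracle_kim(a, labels):
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        if labels[i] == 0:
            continue
        out[i] = sum(a[i, j] for j in range(n)
                     if j != i and labels[j] == labels[i])
    return out


class TestBicor:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        assert cx.bicor_vector(x, x) == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        assert cx.bicor_vector(x, -x) == pytest.approx(-1.0)

    def test_outlier_pair_matches_oracle_and_beats_pearson(self):
        x = [1.0, 2.0, 3.0, 4.0, 100.0]
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        expected = oracle_bicor(x, y)  # frozen: 0.7828107175223246
        assert expected == pytest.approx(0.7828107175223246, abs=1e-12)
        assert cx.bicor_vector(x, y) == pytest.approx(expected, abs=1e-12)
        pearson = float(np.corrcoef(x, y)[0, 1])
        assert abs(cx.bicor_vector(x, y) - 1) < abs(pearson - 1)

    def test_matrix_matches_pairwise_oracle(self, rng):
        X = rng.normal(size=(15, 8))
        cm = cx.correlation_matrix(X, method="bicor")
        for i in range(8):
            for j in range(i + 1, 8):
                assert cm.values[i, j] == pytest.approx(
                    oracle_bicor(X[:, i], X[:, j]), abs=1e-9)

    def test_mad_zero_falls_back_to_pearson(self):
        X = np.column_stack([
            np.array([0.0, 0, 0, 0, 0, 0, 0, 5, 6, 7]),  # mad == 0
            np.arange(10, dtype=float),
        ])
        cm = cx.correlation_matrix(X, method="bicor")
        assert np.isfinite(cm.values).all()

    def test_zero_variance_pearson_warns_and_zeroes(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = cx.correlation_matrix(X, method="pearson")
        assert cm.values[0, 1] == 0.0 and cm.values[0, 0] == 1.0

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="3 samples"):
            cx.correlation_matrix(np.ones((2, 4)))

    def test_symmetry_unit_diagonal_bounds(self, rng):
        X = rng.normal(size=(20, 10))
        for method in ("pearson", "spearman", "bicor"):
            cm = cx.correlation_matrix(X, method=method)
            np.testing.assert_allclose(cm.values, cm.values.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(cm.values), 1.0)
            assert cm.values.min() >= -1 and cm.values.max() <= 1


class TestAdjacency:
    def test_signed_zero_cor(self):
        cm = cx.CorrelationMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]),
                                  "pearson")
        adj = cx.adjacency(cm, "signed", 6)
        assert adj.values[0, 1] == pytest.approx(0.015625)

    def test_unsigned_negative_cor(self):
        cm = cx.CorrelationMatrix(["a", "b"], np.array([[1.0, -0.5], [-0.5, 1.0]]),
                                  "pearson")
        assert cx.adjacency(cm, "unsigned", 2).values[0, 1] == pytest.approx(0.25)

    @pytest.mark.parametrize("beta", [1, 2, 6, 12])
    def test_signed_hybrid_zeroes_negative(self, beta):
        cm = cx.CorrelationMatrix(["a", "b"], np.array([[1.0, -0.9], [-0.9, 1.0]]),
                                  "pearson")
        assert cx.adjacency(cm, "signed_hybrid", beta).values[0, 1] == 0.0

    def test_entries_in_unit_interval(self, rng):
        X = rng.normal(size=(12, 9))
        cm = cx.correlation_matrix(X, method="pearson")
        for nt in ("signed", "signed_hybrid", "unsigned"):
            a = cx.adjacency(cm, nt, 6).values
            assert a.min() >= 0 and a.max() <= 1
            np.testing.assert_allclose(a, a.T, atol=1e-12)

    def test_beta_below_one_errors(self):
        cm = cx.CorrelationMatrix(["a"], np.array([[1.0]]), "pearson")
        with pytest.raises(ValueError):
            cx.adjacency(cm, "signed", 0.5)


class TestTOM:
    def test_complete_triangle(self):
        a = cx.AdjacencyMatrix(list("abc"), np.ones((3, 3)) - np.eye(3), "signed", 1)
        tom = cx.tom_similarity(a)
        assert tom.values[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(tom.values), 1.0)

    def test_single_edge_formula(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.5
        a = cx.AdjacencyMatrix(list("abc"), vals, "signed", 1)
        # (0 + 0.5) / (0.5 + 1 - 0.5) = 0.5
        assert cx.tom_similarity(a).values[0, 1] == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        for n in (6, 12, 20):
            raw = rng.uniform(0, 1, size=(n, n))
            sym = (raw + raw.T) / 2
            np.fill_diagonal(sym, 0.0)
            a = cx.AdjacencyMatrix([f"g{i}" for i in range(n)], sym, "signed", 1)
            np.testing.assert_allclose(cx.tom_similarity(a).values, oracle_tom(sym),
                                       atol=1e-12)

    def test_out_of_range_adjacency_rejected(self):
        a = cx.AdjacencyMatrix(list("ab"), np.array([[0.0, 1.5], [1.5, 0.0]]),
                               "signed", 1)
        with pytest.raises(ValueError):
            cx.tom_similarity(a)


class TestScaleFreeFit:
    def test_power_law_sequence_fits_well(self):
        ks = np.arange(1, 101)
        p = 1.0 / ks
        counts = np.round(p / p.sum() * 100000).astype(int)
        deg = np.repeat(ks.astype(float), counts)
        fit = cx.scale_free_fit(deg, n_bins=10)
        assert fit.r2 >= 0.9 and fit.slope < 0

    def test_binomial_sequence_fits_poorly(self):
        rng = np.random.default_rng(0)
        deg = rng.binomial(499, 0.2, size=500).astype(float)
        assert cx.scale_free_fit(deg, n_bins=10).r2 < 0.5

    def test_degenerate_equal_connectivity_errors(self):
        with pytest.raises(ValueError, match="degenerate|equal"):
            cx.scale_free_fit(np.full(50, 3.0))


class TestSoftThreshold:
    def test_mean_k_monotone_in_power(self, rng):
        X = rng.normal(size=(30, 40))
        cm = cx.correlation_matrix(X, method="pearson")
        res = cx.pick_soft_threshold(cm, "signed", powers=range(1, 11))
        mean_k = res.table["mean_k"].to_numpy()
        assert np.all(np.diff(mean_k) <= 1e-9)

    def test_single_power_forced_choice(self, rng):
        X = rng.normal(size=(30, 40))
        cm = cx.correlation_matrix(X, method="pearson")
        res = cx.pick_soft_threshold(cm, "signed", powers=[6])
        assert res.beta == 6 and len(res.table) == 1

    def test_matches_brute_force_over_powers(self, small_scenario):
        """The chosen power equals an independent exhaustive scan that
        evaluates every power and applies the same smallest-passing rule."""
        from scgrnet import pseudocells
        expr, _ = small_scenario
        rep = pseudocells.make_representative_cells(
            pseudocells.normalize_log1p(expr), "group", 10, seed=1).expr
        cm = cx.correlation_matrix(rep.values, rep.gene_ids, method="bicor")
        powers = list(range(1, 13))
        res = cx.pick_soft_threshold(cm, "signed", powers=powers, r2_cut=0.85)
        # brute force: recompute each power's fit independently
        r2s = {}
        for p in powers:
            adj = cx.adjacency(cm, "signed", p)
            try:
                r2s[p] = cx.scale_free_fit(adj).r2
            except ValueError:
                r2s[p] = float("nan")
        passing = [p for p in powers if r2s[p] >= 0.85]
        if passing:
            assert res.beta == passing[0] and res.passed
        else:
            best = max((p for p in powers if not np.isnan(r2s[p])),
                       key=lambda p: r2s[p])
            assert res.beta == best and not res.passed

    def test_empty_powers_errors(self, rng):
        cm = cx.correlation_matrix(rng.normal(size=(10, 5)), method="pearson")
        with pytest.raises(ValueError):
            cx.pick_soft_threshold(cm, powers=[])


def block_expression(block_sizes, n_samples=50, seed=0):
    """Planted blocks of perfectly correlated genes: cor 1 within a block
    and exactly 0 between (centered, orthogonalized base profiles)."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n_samples, len(block_sizes)))
    raw -= raw.mean(axis=0)
    bases, _ = np.linalg.qr(raw)  # centered + orthogonal columns
    cols, labels = [], []
    for b, size in enumerate(block_sizes, start=1):
        for _ in range(size):
            cols.append(bases[:, b - 1])
            labels.append(b)
    return np.column_stack(cols), np.array(labels)


class TestModuleDetection:
    def test_three_perfect_blocks_recovered(self):
        X, planted = block_expression([35, 32, 30])
        genes = [f"g{i}" for i in range(X.shape[1])]
        cm = cx.correlation_matrix(X, genes, method="pearson")
        tom = cx.tom_similarity(cx.adjacency(cm, "signed", 6))
        mods = cx.detect_modules(tom, X, min_module_size=30)
        assert len(mods.module_ids) == 3
        assert (mods.labels == cx.GREY).sum() == 0
        # labels match planted blocks up to permutation
        for b in (1, 2, 3):
            assert len(set(mods.labels[planted == b])) == 1

    def test_iid_noise_mostly_grey(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 100))
        cm = cx.correlation_matrix(X, method="bicor")
        beta = cx.pick_soft_threshold(cm, "signed").beta
        tom = cx.tom_similarity(cx.adjacency(cm, "signed", beta))
        mods = cx.detect_modules(tom, X, min_module_size=30)
        assert (mods.labels == cx.GREY).mean() >= 0.9

    def test_gene_permutation_invariance(self):
        X, _ = block_expression([32, 30], n_samples=40, seed=3)
        noise = np.random.default_rng(4).normal(size=(40, 20))
        X = np.column_stack([X, noise])
        genes = [f"g{i:02d}" for i in range(X.shape[1])]

        def run(order):
            Xp = X[:, order]
            gp = [genes[i] for i in order]
            cm = cx.correlation_matrix(Xp, gp, method="pearson")
            tom = cx.tom_similarity(cx.adjacency(cm, "signed", 6))
            mods = cx.detect_modules(tom, Xp, min_module_size=20)
            return {g: int(lab) for g, lab in zip(gp, mods.labels)}

        base = run(list(range(X.shape[1])))
        perm = list(np.random.default_rng(5).permutation(X.shape[1]))
        other = run(perm)
        # same partition up to renumbering
        mapping = {}
        for g in genes:
            a, b = base[g], other[g]
            assert mapping.setdefault(a, b) == b


class TestEigengenes:
    def test_identical_genes_rank_one(self, rng):
        v = rng.normal(size=20)
        X = np.column_stack([v] * 5)
        eig, var = cx.module_eigengenes(X, [f"g{i}" for i in range(5)],
                                        np.ones(5, dtype=int))
        assert var["M1"] == pytest.approx(1.0)
        e = eig["M1"].to_numpy()
        assert cx._safe_pearson(e, v) == pytest.approx(1.0)

    def test_antisymmetric_pair(self, rng):
        x = rng.normal(size=15)
        X = np.column_stack([x, -x])
        eig, var = cx.module_eigengenes(X, ["a", "b"], np.array([1, 1]))
        assert var["M1"] == pytest.approx(1.0)
        e = eig["M1"].to_numpy()
        kmes = [cx._safe_pearson(e, X[:, j]) for j in range(2)]
        assert np.mean(kmes) >= 0

    def test_var_explained_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(25, 10))
        _, var = cx.module_eigengenes(X, [f"g{i}" for i in range(10)],
                                      np.ones(10, dtype=int))
        z = (X - X.mean(0)) / X.std(0)
        evals = np.linalg.eigvalsh(z.T @ z)
        assert var["M1"] == pytest.approx(evals[-1] / evals.sum(), abs=1e-9)

    def test_var_explained_in_unit_interval(self, rng):
        X = rng.normal(size=(18, 12))
        labels = np.array([1] * 6 + [2] * 6)
        _, var = cx.module_eigengenes(X, [f"g{i}" for i in range(12)], labels)
        assert ((var > 0) & (var <= 1)).all()
        assert set(var.index) == {"M1", "M2"}  # grey has no eigengene


class TestConnectivityAndHubs:
    def test_complete_module_kim(self):
        n = 5
        a = cx.AdjacencyMatrix([f"g{i}" for i in range(n)],
                               np.ones((n, n)) - np.eye(n), "signed", 1)
        kim = cx.intramodular_connectivity(a, np.ones(n, dtype=int))
        np.testing.assert_allclose(kim.to_numpy(), 4.0)

    def test_kim_matches_brute_force(self, rng):
        n = 12
        raw = rng.uniform(0, 1, (n, n))
        sym = (raw + raw.T) / 2
        np.fill_diagonal(sym, 0)
        labels = rng.integers(0, 3, n)
        a = cx.AdjacencyMatrix([f"g{i}" for i in range(n)], sym, "signed", 1)
        np.testing.assert_allclose(
            cx.intramodular_connectivity(a, labels).to_numpy(),
            oracle_kim(sym, labels), atol=1e-12)

    def test_gene_equal_to_eigengene_has_kme_one(self, rng):
        v = rng.normal(size=20)
        X = np.column_stack([v, v * 2, 3 * v + 1])  # rank-1: eigengene == z(v)
        genes = ["a", "b", "c"]
        labels = np.ones(3, dtype=int)
        eig, _ = cx.module_eigengenes(X, genes, labels)
        kme = cx.module_membership(X, genes, labels, eig, method="pearson")
        assert kme["a"] == pytest.approx(1.0, abs=1e-9)

    def test_concordant_rankings_give_top2(self):
        genes = [f"g{i:02d}" for i in range(20)]
        score = pd.Series(np.arange(20, 0, -1, dtype=float), index=genes)
        hubs = cx.detect_hubs(genes, score, score, top_frac=0.10)
        assert hubs == ["g00", "g01"]

    def test_reversed_rankings_give_empty(self):
        genes = [f"g{i:02d}" for i in range(20)]
        up = pd.Series(np.arange(20, dtype=float), index=genes)
        down = pd.Series(np.arange(20, 0, -1, dtype=float), index=genes)
        assert cx.detect_hubs(genes, up, down, top_frac=0.10) == []

    def test_tiny_module_warns_empty(self):
        s = pd.Series([1.0], index=["g"])
        with pytest.warns(UserWarning):
            assert cx.detect_hubs(["g"], s, s) == []


class TestTraitCorrelation:
    def test_eigengene_equal_to_indicator(self):
        idx = [f"c{i}" for i in range(10)]
        ind = np.array([1.0] * 5 + [0.0] * 5)
        eig = pd.DataFrame({"M1": ind}, index=idx)
        meta = pd.DataFrame({"condition": ["sick"] * 5 + ["well"] * 5}, index=idx)
        out = cx.module_trait_correlation(eig, meta)
        row = out[(out["module"] == "M1") & (out["trait"] == "condition=sick")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_trait_low_correlation(self):
        rng = np.random.default_rng(5)
        idx = [f"c{i}" for i in range(200)]
        eig = pd.DataFrame({"M1": rng.normal(size=200)}, index=idx)
        meta = pd.DataFrame({"x": rng.normal(size=200)}, index=idx)
        out = cx.module_trait_correlation(eig, meta)
        assert abs(out["rho"].iloc[0]) < 0.2 and out["p_adj"].iloc[0] > 0.05

    def test_output_shape_modules_by_traits(self):
        rng = np.random.default_rng(2)
        idx = [f"c{i}" for i in range(30)]
        eig = pd.DataFrame({f"M{m}": rng.normal(size=30) for m in range(1, 28)},
                           index=idx)
        meta = pd.DataFrame({"cond": rng.choice(["a", "b", "c"], 30)}, index=idx)
        out = cx.module_trait_correlation(eig, meta)
        assert len(out) == 27 * 3

    def test_constant_trait_flagged(self):
        idx = [f"c{i}" for i in range(10)]
        eig = pd.DataFrame({"M1": np.arange(10.0)}, index=idx)
        meta = pd.DataFrame({"x": np.ones(10)}, index=idx)
        out = cx.module_trait_correlation(eig, meta)
        assert out["flag"].iloc[0] == "constant" and out["rho"].iloc[0] == 0.0

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(9)
        idx = [f"c{i}" for i in range(40)]
        eig = pd.DataFrame({f"M{m}": rng.normal(size=40) for m in range(1, 6)},
                           index=idx)
        meta = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)},
                            index=idx)
        out = cx.module_trait_correlation(eig, meta)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        s = out.sort_values("p")
        assert (np.diff(s["p_adj"].to_numpy()) >= -1e-12).all()


class TestSubmodule:
    def _cor_with_clique(self, n=90, clique=16, seed=0):
        """Correlation fixture: a clique of genes pairwise >= 0.9, rest below."""
        rng = np.random.default_rng(seed)
        n_samples = 400
        base = rng.normal(size=n_samples)
        cols = []
        for i in range(n):
            if i < clique:
                cols.append(base + 0.1 * rng.normal(size=n_samples))
            else:
                cols.append(rng.normal(size=n_samples))
        X = np.column_stack(cols)
        return cx.correlation_matrix(X, [f"g{i:02d}" for i in range(n)],
                                     method="pearson")

    def test_threshold_zero_keeps_everything(self):
        cm = self._cor_with_clique(n=10, clique=4)
        genes, edges = cx.extract_submodule(cm, cm.genes, 0.0, signed=False)
        assert len(genes) == 10 and len(edges) == 10 * 9 // 2

    def test_threshold_one_of_noise_is_empty(self):
        cm = self._cor_with_clique(n=10, clique=0, seed=3)
        genes, edges = cx.extract_submodule(cm, cm.genes, 1.0)
        assert genes == [] and len(edges) == 0

    def test_ninety_gene_module_sixteen_at_point_nine(self):
        cm = self._cor_with_clique(n=90, clique=16)
        genes, edges = cx.extract_submodule(cm, cm.genes, 0.9)
        assert len(genes) == 16
        assert (edges["correlation"] >= 0.9).all()

    def test_invalid_threshold_errors(self):
        cm = self._cor_with_clique(n=5, clique=2)
        with pytest.raises(ValueError):
            cx.extract_submodule(cm, cm.genes, 1.5)
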