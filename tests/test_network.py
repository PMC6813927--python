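import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import triadnet as tn
from triadnet import network
from conftest import expr_from_array


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Brute-force triple-loop topological overlap."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


class TestBicor:
    def test_self_and_anticorrelation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        expr = expr_from_array(np.vstack([x, x, -x]))
        cor = network.bicor_matrix(expr)
        assert cor.values.iloc[0, 1] == pytest.approx(1.0)
        assert cor.values.iloc[0, 2] == pytest.approx(-1.0)

    def test_close_to_pearson_on_clean_gaussian(self):
        rng = np.random.default_rng(1)
        cov = [[1.0, 0.6], [0.6, 1.0]]
        draws = rng.multivariate_normal([0, 0], cov, size=1000).T
        expr = expr_from_array(draws)
        bic = network.bicor_matrix(expr).values.iloc[0, 1]
        pea = np.corrcoef(draws)[0, 1]
        assert abs(bic - pea) < 0.05

    def test_equals_pearson_when_weights_constant(self):
        # sign-pattern profiles: every deviation from the median has the same
        # magnitude, so all biweights are equal, median = mean, and bicor
        # must reduce to Pearson exactly
        patterns = np.array(
            [
                [1, 1, -1, -1, 1, -1, -1, 1],
                [1, -1, 1, -1, 1, -1, 1, -1],
                [-1, 1, 1, -1, -1, 1, 1, -1],
            ],
            dtype=float,
        )
        expr = expr_from_array(2.5 * patterns + 7.0)
        bic = network.bicor_matrix(expr).values.to_numpy()
        pea = np.corrcoef(expr.values.to_numpy())
        assert np.allclose(bic, pea, atol=1e-12)

    def test_outlier_resistance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = x + rng.normal(scale=0.1, size=50)
        y_corrupt = y.copy()
        y_corrupt[0] = 60.0  # one wild outlier
        expr = expr_from_array(np.vstack([x, y_corrupt]))
        bic = network.bicor_matrix(expr).values.iloc[0, 1]
        pea = np.corrcoef(x, y_corrupt)[0, 1]
        assert bic > 0.9 > pea

    def test_mad_zero_fallback_flagged(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 9.0])
        y = np.arange(6.0)
        cor = network.bicor_matrix(expr_from_array(np.vstack([x, y])))
        assert "g0" in cor.fallback_genes

    def test_zero_variance_flagged(self):
        expr = expr_from_array(np.vstack([np.ones(6), np.arange(6.0)]))
        cor = network.bicor_matrix(expr)
        assert "g0" in cor.zero_variance_genes

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            network.bicor_matrix(expr_from_array(np.ones((2, 3))))


class TestScaleFreeFit:
    def test_exact_power_law_recovered(self):
        # frequencies proportional to k^-2.5 on a geometric grid
        k_values = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 512.0])
        counts = np.round(1e6 * k_values**-2.5).astype(int)
        k = np.repeat(k_values, counts)
        r2, gamma = network.scale_free_fit(k, n_bins=10)
        assert r2 > 0.95
        assert gamma == pytest.approx(2.5, abs=0.3)

    def test_uniform_connectivity_fits_poorly(self):
        rng = np.random.default_rng(3)
        k = rng.uniform(1.0, 100.0, size=2000)
        r2, _ = network.scale_free_fit(k)
        assert r2 < 0.9

    def test_positive_slope_gives_nonpositive_index(self):
        # frequencies increasing with k: log-log slope > 0
        k_values = np.array([1.0, 2.0, 4.0, 8.0])
        counts = np.array([5, 20, 80, 320])
        k = np.repeat(k_values, counts)
        r2, _ = network.scale_free_fit(k, n_bins=4)
        assert r2 <= 0.0

    def test_constant_connectivity_rejected(self):
        with pytest.raises(ValueError):
            network.scale_free_fit(np.ones(50))


class TestAdjacency:
    def test_examples(self):
        frame = pd.DataFrame(
            [[1.0, 0.5, -0.8], [0.5, 1.0, 1.0], [-0.8, 1.0, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        cor = network.CorrelationMatrix(frame, "pearson")
        adj = network.adjacency(cor, beta=7, network_type="signed_hybrid")
        assert adj.values.at["a", "b"] == pytest.approx(0.5**7)  # 1/128
        assert adj.values.at["a", "c"] == 0.0  # negative truncation
        assert adj.values.at["b", "c"] == 1.0
        uns = network.adjacency(cor, beta=2, network_type="unsigned")
        assert uns.values.at["a", "c"] == pytest.approx(0.64)

    def test_monotone_in_correlation(self):
        s = np.linspace(0.05, 0.95, 10)
        a = s**6
        assert (np.diff(a) > 0).all()

    def test_connectivity_excludes_diagonal(self):
        frame = pd.DataFrame(np.full((3, 3), 0.5), index=list("abc"), columns=list("abc"))
        np.fill_diagonal(frame.to_numpy(), 1.0)
        adj = network.adjacency(network.CorrelationMatrix(frame, "pearson"), beta=1)
        assert np.allclose(adj.connectivity, 1.0)  # 2 neighbors x 0.5


class TestTOM:
    def test_two_gene_saturated_edge(self):
        frame = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=list("ab"), columns=list("ab"))
        tom = network.tom_similarity(frame)
        assert tom.similarity.at["a", "b"] == pytest.approx(1.0)

    def test_disconnected_network(self):
        frame = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        tom = network.tom_similarity(frame)
        off = tom.similarity.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(5, 9))
            a = rng.uniform(0.0, 1.0, size=(n, n))
            a = (a + a.T) / 2.0
            np.fill_diagonal(a, 0.0)
            frame = pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                                 columns=[f"g{i}" for i in range(n)])
            tom = network.tom_similarity(frame).similarity.to_numpy()
            assert np.max(np.abs(tom - tom_oracle(a))) < 1e-12

    def test_asymmetric_input_rejected(self):
        frame = pd.DataFrame([[0.0, 0.5], [0.2, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            network.tom_similarity(frame)


def block_dissimilarity(sizes, within=0.2, between=0.95, seed=0):
    """Synthetic 1-TOM with planted blocks."""
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    d = np.full((n, n), between) + rng.uniform(-0.02, 0.02, size=(n, n))
    start = 0
    truth = np.zeros(n, dtype=int)
    for b, size in enumerate(sizes, start=1):
        block = slice(start, start + size)
        d[block, block] = within + rng.uniform(-0.02, 0.02, size=(size, size))
        truth[block] = b
        start += size
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    genes = [f"g{i:03d}" for i in range(n)]
    return pd.DataFrame(d, index=genes, columns=genes), truth


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        diss, truth = block_dissimilarity([40, 40])
        part = network.detect_modules(diss, min_module_size=30)
        assert len(part.modules) == 2
        assert adjusted_rand_score(truth, part.labels.to_numpy()) == 1.0

    def test_small_cluster_goes_to_module_zero(self):
        diss, _ = block_dissimilarity([40, 29])
        part = network.detect_modules(diss, min_module_size=30)
        assert len(part.modules) == 1
        assert part.module_sizes().iloc[0] == 40
        assert (part.labels == 0).sum() == 29

    def test_identical_profiles_single_module(self):
        n = 35
        d = pd.DataFrame(np.zeros((n, n)),
                         index=[f"g{i}" for i in range(n)],
                         columns=[f"g{i}" for i in range(n)])
        part = network.detect_modules(d, min_module_size=30)
        assert part.modules == [1]
        assert part.n_assigned == n

    def test_labels_ordered_by_size(self):
        diss, _ = block_dissimilarity([30, 60, 45])
        part = network.detect_modules(diss, min_module_size=30)
        sizes = part.module_sizes()
        assert list(sizes.index) == [1, 2, 3]
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_nonfinite_rejected(self):
        d = pd.DataFrame(np.full((3, 3), np.nan), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            network.detect_modules(d, min_module_size=2)


class TestEigengenes:
    def make_module_expr(self, profile, n_genes=10, noise=0.05, seed=5):
        rng = np.random.default_rng(seed)
        rows = [profile + rng.normal(scale=noise, size=len(profile)) for _ in range(n_genes)]
        return expr_from_array(np.array(rows))

    def test_recovers_common_profile(self):
        rng = np.random.default_rng(6)
        profile = rng.normal(size=20)
        expr = self.make_module_expr(profile)
        part = network.ModulePartition({g: 1 for g in expr.gene_ids})
        eig = network.module_eigengenes(expr, part)
        me = eig.values.loc[1].to_numpy()
        assert abs(np.corrcoef(me, profile)[0, 1]) > 0.99
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_orientation_mean_member_correlation_nonnegative(self):
        rng = np.random.default_rng(7)
        profile = rng.normal(size=15)
        expr = self.make_module_expr(profile, seed=8)
        part = network.ModulePartition({g: 1 for g in expr.gene_ids})
        me = network.module_eigengenes(expr, part).values.loc[1]
        cors = [np.corrcoef(expr.values.loc[g], me)[0, 1] for g in expr.gene_ids]
        assert np.mean(cors) > 0
        flipped = expr_from_array(-expr.values.to_numpy())
        me_flipped = network.module_eigengenes(flipped, network.ModulePartition(
            {g: 1 for g in flipped.gene_ids})).values.loc[1]
        assert np.allclose(me_flipped.to_numpy(), -me.to_numpy(), atol=1e-9)

    def test_variance_explained_matches_eigendecomposition(self):
        rng = np.random.default_rng(9)
        expr = expr_from_array(rng.normal(size=(8, 12)))
        part = network.ModulePartition({g: 1 for g in expr.gene_ids})
        eig = network.module_eigengenes(expr, part)
        x = expr.values.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        evals = np.linalg.eigvalsh(z @ z.T)
        assert eig.variance_explained[1] == pytest.approx(evals[-1] / evals.sum())
        assert 0.0 < eig.variance_explained[1] <= 1.0

    def test_eigengene_is_variance_maximizing(self):
        rng = np.random.default_rng(10)
        expr = expr_from_array(rng.normal(size=(6, 15)))
        part = network.ModulePartition({g: 1 for g in expr.gene_ids})
        eig = network.module_eigengenes(expr, part)
        x = expr.values.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        me_var = ((z @ eig.values.loc[1].to_numpy()) ** 2).sum()
        for row in z:
            u = row / np.linalg.norm(row)
            assert ((z @ u) ** 2).sum() <= me_var + 1e-9

    def test_zero_variance_module_flagged(self):
        expr = expr_from_array(np.ones((3, 6)))
        part = network.ModulePartition({g: 1 for g in expr.gene_ids})
        eig = network.module_eigengenes(expr, part)
        assert eig.flagged_modules == [1]


class TestMergeModules:
    def test_duplicate_factor_modules_merged(self):
        rng = np.random.default_rng(11)
        factor = rng.normal(size=25)
        rows = [factor + rng.normal(scale=0.1, size=25) for _ in range(20)]
        expr = expr_from_array(np.array(rows))
        labels = {g: (1 if i < 10 else 2) for i, g in enumerate(expr.gene_ids)}
        part = network.ModulePartition(labels)
        merged = network.merge_modules(part, expr, merge_cut_height=0.15)
        assert len(merged.modules) == 1

    def test_orthogonal_factor_modules_unchanged(self):
        rng = np.random.default_rng(12)
        f1, f2 = rng.normal(size=(2, 25))
        rows = [f1 + rng.normal(scale=0.1, size=25) for _ in range(10)]
        rows += [f2 + rng.normal(scale=0.1, size=25) for _ in range(10)]
        expr = expr_from_array(np.array(rows))
        part = network.ModulePartition(
            {g: (1 if i < 10 else 2) for i, g in enumerate(expr.gene_ids)}
        )
        eig = network.module_eigengenes(expr, part)
        assert np.corrcoef(eig.values.loc[1], eig.values.loc[2])[0, 1] < 0.85
        merged = network.merge_modules(part, expr, merge_cut_height=0.15)
        assert len(merged.modules) == 2

    def test_tiny_cut_height_leaves_partition_unchanged(self):
        rng = np.random.default_rng(13)
        expr = expr_from_array(rng.normal(size=(20, 25)))
        part = network.ModulePartition(
            {g: (1 if i < 10 else 2) for i, g in enumerate(expr.gene_ids)}
        )
        merged = network.merge_modules(part, expr, merge_cut_height=1e-9)
        assert (merged.labels.value_counts().sort_index()
                == part.labels.value_counts().sort_index()).all()


class TestKME:
    def test_eigengene_itself_and_negation(self):
        rng = np.random.default_rng(14)
        profile = rng.normal(size=20)
        rows = np.vstack([profile + rng.normal(scale=0.01, size=20) for _ in range(5)])
        expr = expr_from_array(rows)
        part = network.ModulePartition({g: 1 for g in expr.gene_ids})
        eig = network.module_eigengenes(expr, part)
        me = eig.values.loc[1].to_numpy()
        pseudo = expr_from_array(np.vstack([me, -me]), genes=["me", "neg"])
        kme = network.signed_kme(pseudo, eig)
        assert kme.at["me", 1] == pytest.approx(1.0)
        assert kme.at["neg", 1] == pytest.approx(-1.0)

    def test_random_gene_kme_near_zero(self):
        rng = np.random.default_rng(15)
        n = 400
        me = rng.normal(size=n)
        eig = network.EigengeneMatrix(
            pd.DataFrame([me / np.linalg.norm(me)], index=[1],
                         columns=[f"s{j}" for j in range(n)]),
            pd.Series({1: 1.0}),
        )
        gene = expr_from_array(rng.normal(size=(1, n)))
        kme = network.signed_kme(gene, eig)
        assert abs(kme.iloc[0, 0]) < 3 / np.sqrt(n)


class TestHubGenes:
    def test_ranking_and_truncation(self):
        kme = pd.DataFrame({1: [0.7, 0.9, 0.8]}, index=["c", "a", "b"])
        part = network.ModulePartition({"a": 1, "b": 1, "c": 1})
        assert network.hub_genes(kme, part, n=2) == {1: ["a", "b"]}
        assert network.hub_genes(kme, part, n=10) == {1: ["a", "b", "c"]}

    def test_ties_broken_lexicographically(self):
        kme = pd.DataFrame({1: [0.5, 0.5, 0.5]}, index=["z", "m", "a"])
        part = network.ModulePartition({"z": 1, "m": 1, "a": 1})
        assert network.hub_genes(kme, part, n=3) == {1: ["a", "m", "z"]}

    def test_high_loading_gene_ranks_high(self):
        # at the latent level (gene = loading x factor + noise) kME is
        # monotone in loading, so the top-loading gene must rank in the top
        # decile of its module; many samples keep sampling noise below the
        # loading spacing
        from triadnet import datasets

        config = datasets.SynthConfig(
            tissue_labels=("a", "b", "c", "d"),
            n_samples_per_tissue=75,
            module_specs=[datasets.ModuleSpec(1, 80), datasets.ModuleSpec(2, 80)],
            n_background_genes=0,
            triad_fraction=0.0,
        )
        rng = np.random.default_rng(20)
        planted = datasets.plant_modules(config, rng)
        noise = rng.normal(scale=config.noise_sd, size=planted.signal.shape)
        expr = tn.ExpressionMatrix(planted.signal + noise, unit="normalized")
        eig = network.module_eigengenes(expr, planted.partition)
        kme = network.signed_kme(expr, eig)
        for m in planted.partition.modules:
            members = planted.partition.genes_in(m)
            top_loading = max(members, key=lambda g: planted.loadings[g])
            ranked = sorted(members, key=lambda g: -kme.at[g, m])
            assert ranked.index(top_loading) < max(1, int(0.1 * len(members)))
        # and loading ordering is globally respected
        from scipy.stats import spearmanr

        for m in planted.partition.modules:
            members = planted.partition.genes_in(m)
            rho = spearmanr(
                [planted.loadings[g] for g in members],
                [kme.at[g, m] for g in members],
            ).statistic
            assert rho > 0.9


class TestSoftThreshold:
    def test_independent_noise_never_reaches_target(self):
        rng = np.random.default_rng(16)
        expr = expr_from_array(rng.normal(size=(120, 30)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = network.pick_soft_threshold(expr, powers=range(1, 11))
        assert scan.chosen_beta is None

    def test_modular_data_mean_connectivity_decreases(self, fitted):
        _, res = fitted
        scan = res.scan
        assert scan is not None and scan.chosen_beta is not None
        assert (np.diff(scan.table["mean_k"]) < 0).all()

    def test_trivial_target_picks_first_power(self, fitted):
        _, res = fitted
        model = tn.CoexpressionNetwork(res.expr)
        scan = model.pick_soft_threshold(powers=[2, 4, 6], target_fit=-np.inf)
        assert scan.chosen_beta == 2


class TestModelShape:
    def test_results_carry_partition_and_summary(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "modules" in text and "beta" in text
        assert set(res.kme.columns) == set(res.partition.modules)
        assert res.eigengenes.values.shape[1] == res.expr.n_samples
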