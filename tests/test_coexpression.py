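import numpy as np
import pandas as pd
import pytest

from plastex.coexpression import (
    NetworkParams,
    adjacency_from_expr,
    build_tom,
    classify_preservation,
    detect_modules,
    filter_coexpression_genes,
    hub_genes,
    module_preservation,
    pick_soft_power,
    scale_free_fit,
    tom_from_adjacency,
    transform_counts,
)
from plastex.datatypes import PlastexError

from helpers import (
    block_expression,
    count_matrix,
    hetero_block_expression,
    make_design,
    nb_counts,
)


def brute_force_tom(a):
    """Element-wise evaluation of the TOM formula."""
    a = np.asarray(a, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(
                a[i, u] * a[u, j] for u in range(n) if u not in (i, j)
            )
            tom[i, j] = (shared + a[i, j]) / (
                min(k[i], k[j]) + 1 - a[i, j]
            )
    return tom


class TestFilterGenes:
    @staticmethod
    def build_pair(rng, n_genes=50):
        dm = make_design(n_groups=1, reps=3, taxon="maize")
        dt = make_design(n_groups=1, reps=3, taxon="teosinte")
        mm = rng.integers(1, 50, size=(n_genes, 6))
        mt = rng.integers(1, 50, size=(n_genes, 6))
        return dm, dt, mm, mt

    def test_gene_zero_in_one_group_removed(self, rng):
        dm, dt, mm, mt = self.build_pair(rng)
        eh_cols = [
            i for i, s in enumerate(dm.sample_ids) if "_EH_" in s
        ]
        mm[0, eh_cols] = 0  # silent in maize-EH
        retained = filter_coexpression_genes(
            count_matrix(mm, sample_ids=dm.sample_ids),
            count_matrix(mt, sample_ids=dt.sample_ids),
            dm, dt,
        )
        assert "G0001" not in retained

    def test_gene_nonzero_somewhere_in_all_groups_retained(self, rng):
        dm, dt, mm, mt = self.build_pair(rng)
        mm[1, :] = 0
        mt[1, :] = 0
        # exactly one nonzero sample per group suffices
        for design, mat in ((dm, mm), (dt, mt)):
            for cond in ("EH", "MA"):
                col = next(
                    i for i, s in enumerate(design.sample_ids)
                    if f"_{cond}_" in s
                )
                mat[1, col] = 1
        retained = filter_coexpression_genes(
            count_matrix(mm, sample_ids=dm.sample_ids),
            count_matrix(mt, sample_ids=dt.sample_ids),
            dm, dt,
        )
        assert "G0002" in retained

    def test_matches_brute_force_recount(self, rng):
        dm = make_design(n_groups=2, reps=2, taxon="maize")
        dt = make_design(n_groups=2, reps=2, taxon="teosinte")
        mm = rng.integers(0, 3, size=(200, 8))
        mt = rng.integers(0, 3, size=(200, 8))
        cm = count_matrix(mm, sample_ids=dm.sample_ids)
        ct = count_matrix(mt, sample_ids=dt.sample_ids)
        retained = filter_coexpression_genes(cm, ct, dm, dt)

        expected = 0
        for g in range(200):
            ok = True
            for design, mat in ((dm, mm), (dt, mt)):
                for cond in ("EH", "MA"):
                    cols = [i for i, s in enumerate(design.sample_ids)
                            if f"_{cond}_" in s]
                    if not (mat[g, cols] > 0).any():
                        ok = False
            expected += ok
        assert len(retained) == expected


class TestTransform:
    def test_zero_maps_to_zero(self):
        cm = count_matrix(np.array([[0, 3], [5, 0]]))
        sf = pd.Series(1.0, index=cm.sample_ids)
        expr = transform_counts(cm, sf)
        assert expr.iloc[0, 0] == 0.0
        assert expr.iloc[1, 1] == 0.0

    def test_rank_order_preserved_per_sample(self, rng):
        cm = count_matrix(rng.integers(0, 1000, size=(30, 4)))
        sf = pd.Series(rng.uniform(0.5, 2.0, 4), index=cm.sample_ids)
        expr = transform_counts(cm, sf)
        for j in range(4):
            raw_ranks = pd.Series(cm.values[:, j]).rank(method="average")
            t_ranks = expr.iloc[:, j].rank(method="average")
            assert (raw_ranks.to_numpy() == t_ranks.to_numpy()).all()

    def test_variance_flattening_on_nb_counts(self, rng):
        n_genes, n_samples = 400, 20
        mu = rng.lognormal(np.log(50), 1.5, n_genes)
        mat = nb_counts(
            np.broadcast_to(mu[:, None], (n_genes, n_samples)).copy(),
            0.3, rng,
        )
        cm = count_matrix(mat)
        sf = pd.Series(1.0, index=cm.sample_ids)
        expr = transform_counts(cm, sf)

        def sd_vs_mean_slope(means, sds):
            keep = means > 0
            return np.polyfit(means[keep], sds[keep], 1)[0]

        raw_slope = sd_vs_mean_slope(mat.mean(axis=1), mat.std(axis=1))
        t_slope = sd_vs_mean_slope(
            expr.mean(axis=1).to_numpy(), expr.std(axis=1).to_numpy()
        )
        assert abs(t_slope) < abs(raw_slope)


class TestTom:
    def test_two_perfectly_correlated_genes(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        tom = tom_from_adjacency(a)
        assert tom[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        assert np.allclose(tom_from_adjacency(a), brute_force_tom(a),
                           atol=1e-12)

    def test_bounds_symmetry_diagonal(self, rng):
        expr, _ = block_expression([10, 10], 15, rng=rng)
        _, tom = build_tom(expr, NetworkParams(beta=4, min_module_size=5))
        t = tom.to_numpy()
        assert np.allclose(t, t.T)
        assert np.allclose(np.diag(t), 1.0)
        assert (t >= 0).all() and (t <= 1 + 1e-12).all()

    def test_beta_one_adjacency_is_abs_correlation(self, rng):
        expr, _ = block_expression([8, 8], 12, rng=rng)
        adj = adjacency_from_expr(expr, beta=1)
        cor = np.corrcoef(expr.to_numpy())
        off = ~np.eye(16, dtype=bool)
        assert np.allclose(adj.to_numpy()[off], np.abs(cor)[off])

    def test_too_few_samples_rejected(self, rng):
        expr, _ = block_expression([5], 2, rng=rng)
        with pytest.raises(PlastexError):
            build_tom(expr, NetworkParams(beta=2))


class TestSoftPower:
    @staticmethod
    def heavy_tailed_expression(rng, n_genes=300, n_samples=40):
        """A few strong latent factors with power-law loadings produce a
        heavy-tailed connectivity distribution."""
        factors = rng.normal(0, 1, (5, n_samples))
        loadings = (rng.pareto(2.0, n_genes) + 0.05)
        loadings = np.minimum(loadings / loadings.max(), 1.0)
        rows = []
        for g in range(n_genes):
            f = factors[g % 5]
            w = loadings[g]
            rows.append(w * f + np.sqrt(max(1 - w**2, 1e-6))
                        * rng.normal(0, 1, n_samples))
        return pd.DataFrame(
            rows, index=[f"G{i}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n_samples)],
        )

    def test_some_beta_reaches_threshold_and_r2_matches_oracle(self, rng):
        expr = self.heavy_tailed_expression(rng)
        beta, fits = pick_soft_power(
            expr, candidate_betas=range(1, 31), r2_threshold=0.8
        )
        assert (fits["r2"] >= 0.8).any()
        # brute-force recomputation of the reported fit at the chosen beta
        cor = np.abs(np.corrcoef(expr.to_numpy()))
        np.fill_diagonal(cor, 0.0)
        k = (cor**beta).sum(axis=1)
        r2, slope = scale_free_fit(k)
        row = fits.loc[fits["beta"] == beta].iloc[0]
        assert row["r2"] == pytest.approx(r2, rel=1e-12)
        assert row["slope"] == pytest.approx(slope, rel=1e-12)

    def test_fallback_to_max_candidate_with_warning(self, rng):
        expr, _ = block_expression([15, 15], 20, within_cor=0.5, rng=rng)
        with pytest.warns(UserWarning, match="largest candidate"):
            beta, _ = pick_soft_power(
                expr, candidate_betas=[1, 2], r2_threshold=0.999999
            )
        assert beta == 2

    def test_single_candidate_returned(self, rng):
        expr, _ = block_expression([15, 15], 20, rng=rng)
        beta, fits = pick_soft_power(
            expr, candidate_betas=[3], r2_threshold=-1.0
        )
        assert beta == 3
        assert len(fits) == 1

    def test_fewer_genes_than_bins_rejected(self, rng):
        expr, _ = block_expression([4], 10, rng=rng)
        with pytest.raises(PlastexError, match="bins"):
            pick_soft_power(expr, candidate_betas=[1, 2], n_bins=10)


class TestDetectModules:
    def test_planted_two_block_recovery(self, rng):
        from sklearn.metrics import adjusted_rand_score

        expr, labels = block_expression([100, 100], 30, within_cor=0.9,
                                        rng=rng)
        params = NetworkParams(beta=6, min_module_size=30)
        _, tom = build_tom(expr, params)
        modules = detect_modules(1 - tom, expr, params)
        found = modules.labels.loc[expr.index].to_numpy()
        assert len(modules.modules()) == 2
        assert adjusted_rand_score(labels, found) >= 0.9

    def test_similar_eigengene_modules_merged(self, rng):
        """Two planted blocks driven by latent factors correlated at 0.9
        end up merged (eigengene dissimilarity 0.1 < 0.25)."""
        n_samples = 40
        shared = rng.normal(0, 1, n_samples)
        rows = []
        for b in range(2):
            own = rng.normal(0, 1, n_samples)
            factor = np.sqrt(0.9) * shared + np.sqrt(0.1) * own
            for _ in range(60):
                rows.append(
                    np.sqrt(0.9) * factor
                    + np.sqrt(0.1) * rng.normal(0, 1, n_samples)
                )
        expr = pd.DataFrame(
            rows, index=[f"G{i}" for i in range(120)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
        params = NetworkParams(beta=6, min_module_size=20,
                               merge_cutoff=0.25,
                               cut_height_quantile=0.90)
        _, tom = build_tom(expr, params)
        modules = detect_modules(1 - tom, expr, params)
        assert len(modules.modules()) == 1

    def test_min_size_above_n_genes_unassigns_all(self, rng):
        expr, _ = block_expression([10], 12, rng=rng)
        params = NetworkParams(beta=2, min_module_size=50)
        with pytest.warns(UserWarning, match="unassigned"):
            modules = detect_modules(
                pd.DataFrame(np.zeros((10, 10)), index=expr.index,
                             columns=expr.index),
                expr, params,
            )
        assert (modules.labels == 0).all()

    def test_deterministic(self, rng):
        expr, _ = block_expression([40, 40], 25, rng=rng)
        params = NetworkParams(beta=4, min_module_size=10)
        _, tom = build_tom(expr, params)
        a = detect_modules(1 - tom, expr, params)
        b = detect_modules(1 - tom, expr, params)
        assert a.labels.equals(b.labels)
        assert a.eigengenes.equals(b.eigengenes)

    def test_eigengene_unit_norm_and_orientation(self, rng):
        expr, _ = block_expression([50], 20, rng=rng)
        params = NetworkParams(beta=4, min_module_size=10)
        _, tom = build_tom(expr, params)
        modules = detect_modules(1 - tom, expr, params)
        for col in modules.eigengenes.columns:
            eig = modules.eigengenes[col].to_numpy()
            assert np.linalg.norm(eig) == pytest.approx(1.0)
            module = int(col.removeprefix("ME"))
            member_mean = expr.loc[modules.genes_in(module)].mean(axis=0)
            assert np.corrcoef(eig, member_mean)[0, 1] > 0


class TestPreservation:
    @staticmethod
    def planted_network(rng, block_sizes=(30, 30), n_noise=240,
                        n_samples=30):
        """Planted modules (known labels) in a noise-dominated universe;
        preservation is tested against the ground-truth assignment so the
        statistic is exercised in isolation from module detection."""
        from plastex.coexpression import ModuleAssignment

        expr, labels = hetero_block_expression(
            list(block_sizes), n_noise, n_samples, rng
        )
        modules = ModuleAssignment(labels=labels, eigengenes=pd.DataFrame())
        params = NetworkParams(beta=8, min_module_size=20,
                               n_permutations=200, seed=0)
        return expr, modules, params

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_noisy_copy_highly_preserved(self, seed):
        rng = np.random.default_rng(seed)
        full, modules, params = self.planted_network(rng)
        assert len(modules.modules()) >= 1
        sd = full.to_numpy().std()
        test = full + rng.normal(0, 0.1 * sd, full.shape)
        results = module_preservation(full, test, modules, params)
        assert results
        assert all(r.z_summary > 10 for r in results)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_permuted_labels_destroy_preservation(self, seed):
        rng = np.random.default_rng(seed)
        full, modules, params = self.planted_network(rng)
        perm = rng.permutation(full.shape[0])
        test = pd.DataFrame(full.to_numpy()[perm], index=full.index,
                            columns=full.columns)
        results = module_preservation(full, test, modules, params)
        assert results
        assert all(r.z_summary < 2 for r in results)

    def test_classification_bands(self):
        assert classify_preservation(1.999) == "none"
        assert classify_preservation(2.0) == "moderate"
        assert classify_preservation(10.0) == "moderate"
        assert classify_preservation(10.001) == "high"

    def test_preservation_seed_reproducible(self, rng):
        full, modules, params = self.planted_network(rng)
        a = module_preservation(full, full, modules, params)
        b = module_preservation(full, full, modules, params)
        assert [(r.module, r.z_summary) for r in a] == [
            (r.module, r.z_summary) for r in b
        ]


class TestHubGenes:
    def test_argmax_first_in_three_gene_module(self):
        genes = ["A", "B", "C"]
        adj = pd.DataFrame(
            [[1.0, 0.9, 0.8], [0.9, 1.0, 0.1], [0.8, 0.1, 1.0]],
            index=genes, columns=genes,
        )
        labels = pd.Series([1, 1, 1], index=genes)
        eig = pd.DataFrame()
        from plastex.coexpression import ModuleAssignment

        modules = ModuleAssignment(labels=labels, eigengenes=eig)
        hubs = hub_genes(adj, modules, top_n=3)
        assert hubs[1][0] == "A"

    def test_matches_brute_force_on_random_module(self, rng):
        from plastex.coexpression import ModuleAssignment

        n = 20
        genes = [f"G{i:02d}" for i in range(n)]
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=genes, columns=genes)
        modules = ModuleAssignment(
            labels=pd.Series([1] * n, index=genes),
            eigengenes=pd.DataFrame(),
        )
        hubs = hub_genes(adj, modules, top_n=n)
        k = a.sum(axis=1) - 1.0
        expected = [g for g, _ in sorted(zip(genes, k),
                                         key=lambda t: (-t[1], t[0]))]
        assert hubs[1] == expected

    def test_top_n_larger_than_module_returns_all(self):
        from plastex.coexpression import ModuleAssignment

        genes = ["A", "B"]
        adj = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=genes,
                           columns=genes)
        modules = ModuleAssignment(
            labels=pd.Series([1, 1], index=genes),
            eigengenes=pd.DataFrame(),
        )
        assert len(hub_genes(adj, modules, top_n=10)[1]) == 2
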