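"""Embedding analytics: similarity oracles, networks, power law, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage

import phenoformer as pf
from phenoformer.analysis import (
    EmbeddingTable,
    _merge_small_clusters,
    aggregate_by_context,
    entity_context_vector,
    gene_context_embeddings,
)
from phenoformer.powerlaw import fit_power_law, sample_discrete_power_law


def _toy_table(seed=0, n_cells=60, h=8):
    """Hand-built embedding table: 2 genes + 1 phenotype slot per cell."""
    rng = np.random.default_rng(seed)
    tissues = np.array(["t1", "t2", "t3"])[rng.integers(0, 3, n_cells)]
    meta = pd.DataFrame({"tissue": tissues, "cell_type": ["ct"] * n_cells})
    vecs, idx, role = [], [], []
    for i in range(n_cells):
        for r in ("tissue", "gA", "gB"):
            vecs.append(rng.normal(size=h))
            idx.append(i)
            role.append(r)
    vectors = np.array(vecs)
    cell_vectors = np.vstack(
        [vectors[np.array(idx) == i].mean(0) for i in range(n_cells)]
    )
    return EmbeddingTable(
        vectors=vectors,
        cell_index=np.array(idx),
        role=np.array(role),
        metadata=meta,
        cell_vectors=cell_vectors,
        cell_ids=[f"c{i}" for i in range(n_cells)],
        fields=["tissue", "cell_type"],
    )


class TestSimilarityPrimitives:
    def test_cosine_identity_orthogonal_antipodal(self):
        a = np.array([1.0, 0.0, 2.0])
        assert np.isclose(pf.cosine_similarity(a, a), 1.0)
        assert np.isclose(pf.cosine_similarity([1, 0], [0, 1]), 0.0)
        assert np.isclose(pf.cosine_similarity(a, -a), -1.0)

    def test_cosine_zero_vector_rejected(self):
        with pytest.raises(pf.ValidationError):
            pf.cosine_similarity([0.0, 0.0], [1.0, 0.0])

    def test_euclidean_matches_brute_force_and_triangle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 6))
            d = pf.embedding_distance(a, b)
            assert np.isclose(d, np.sqrt(((a - b) ** 2).sum()), atol=1e-10)
            assert pf.embedding_distance(a, c) <= d + pf.embedding_distance(b, c) + 1e-12
        assert pf.embedding_distance(a, a) == 0.0


class TestAggregation:
    def test_single_member_group_mean_is_that_row(self):
        table = _toy_table()
        ctx = aggregate_by_context(table, "gA", ["tissue"], min_support=1)
        one = [c for c in ctx if c.n_cells == 1]
        for c in one:
            cells = table.cells_matching({"tissue": c.context[0]})
            rows = table.rows_for("gA", cells)
            assert np.allclose(c.vector, table.vectors[rows[0]])

    def test_split_and_weighted_average_recovers_full_mean(self):
        table = _toy_table(seed=2)
        full = entity_context_vector(table, "gA", {"tissue": "t1"})
        cells = table.cells_matching({"tissue": "t1"})
        half1, half2 = cells[: len(cells) // 2], cells[len(cells) // 2 :]
        r1 = table.rows_for("gA", half1)
        r2 = table.rows_for("gA", half2)
        m = (
            table.vectors[r1].mean(0) * len(r1) + table.vectors[r2].mean(0) * len(r2)
        ) / (len(r1) + len(r2))
        assert np.allclose(full, m, atol=1e-12)

    def test_support_counts_partition_member_rows(self):
        table = _toy_table(seed=3)
        ctx = aggregate_by_context(table, "gB", ["tissue"], min_support=1)
        assert sum(c.n_cells for c in ctx) == len(table.rows_for("gB"))

    def test_unknown_entity_rejected(self):
        with pytest.raises(pf.SchemaError):
            aggregate_by_context(_toy_table(), "nosuch", ["tissue"])


class TestPhenotypeGeneSimilarity:
    def test_gene_identical_to_phenotype_ranks_first(self):
        rng = np.random.default_rng(4)
        h, n = 6, 30
        tissues = np.array(["a", "b"])[rng.integers(0, 2, n)]
        meta = pd.DataFrame({"tissue": tissues})
        vecs, idx, role = [], [], []
        base = {"a": rng.normal(size=h), "b": rng.normal(size=h)}
        for i in range(n):
            t = tissues[i]
            vecs += [base[t], base[t], rng.normal(size=h)]
            idx += [i, i, i]
            role += ["tissue", "gTwin", "gNoise"]
        vectors = np.array(vecs)
        table = EmbeddingTable(
            vectors=vectors,
            cell_index=np.array(idx),
            role=np.array(role),
            metadata=meta,
            cell_vectors=np.zeros((n, h)),
            cell_ids=[str(i) for i in range(n)],
            fields=["tissue"],
        )
        mat, ranking = pf.phenotype_gene_similarity(table, "tissue")
        assert mat.shape == (2, 2)
        assert ranking.index[0] == "gTwin"
        assert np.isclose(ranking.loc["gTwin", "universal"], 1.0)

    def test_matrix_shape_covers_present_genes_and_values(self):
        table = _toy_table(seed=5)
        mat, _ = pf.phenotype_gene_similarity(table, "tissue")
        assert set(mat.columns) == {"t1", "t2", "t3"}
        assert set(mat.index) == {"gA", "gB"}


class TestDifferentialEmbedding:
    def test_identical_context_embeddings_score_zero(self):
        v = np.ones(5)
        assert pf.differential_embedding_score([v, v, v]) == pytest.approx(0.0)

    def test_antipodal_contexts_score_two(self):
        v = np.array([1.0, 2.0, -1.0])
        assert pf.differential_embedding_score([v, -v]) == pytest.approx(2.0)

    def test_matches_brute_force_pairwise_mean(self):
        rng = np.random.default_rng(6)
        vecs = rng.normal(size=(5, 7))
        sims = [
            pf.cosine_similarity(vecs[i], vecs[j])
            for i, j in itertools.combinations(range(5), 2)
        ]
        assert np.isclose(
            pf.differential_embedding_score(vecs), 1 - np.mean(sims), atol=1e-12
        )

    def test_single_context_rejected(self):
        with pytest.raises(pf.SupportError):
            pf.differential_embedding_score([np.ones(3)])

    def test_context_switching_gene_outranks_stable_genes(self):
        """A gene whose embedding flips direction between tissues scores
        above genes with stable embeddings."""
        rng = np.random.default_rng(7)
        h, n = 6, 40
        tissues = np.array(["a", "b"])[np.arange(n) % 2]
        meta = pd.DataFrame({"tissue": tissues})
        flip = rng.normal(size=h)
        stable = rng.normal(size=h)
        vecs, idx, role = [], [], []
        for i in range(n):
            sgn = 1.0 if tissues[i] == "a" else -1.0
            vecs += [
                sgn * flip + 0.05 * rng.normal(size=h),
                stable + 0.05 * rng.normal(size=h),
            ]
            idx += [i, i]
            role += ["gSwitch", "gStable"]
        table = EmbeddingTable(
            vectors=np.array(vecs),
            cell_index=np.array(idx),
            role=np.array(role),
            metadata=meta,
            cell_vectors=np.zeros((n, h)),
            cell_ids=[str(i) for i in range(n)],
            fields=["tissue"],
        )
        scores = pf.differential_embedding_scores(table, "tissue")
        assert scores.index[0] == "gSwitch"
        assert scores["gSwitch"] > scores["gStable"]


class TestTissueSimilarity:
    def test_matrix_symmetric_unit_diagonal(self):
        table = _toy_table(seed=8)
        df, Z = pf.tissue_similarity_matrix(table)
        assert np.allclose(df.values, df.values.T)
        assert np.allclose(np.diag(df.values), 1.0)

    def test_duplicated_tissue_has_correlation_one(self):
        # the same cells filed under two tissue labels correlate at exactly 1
        table = _toy_table(seed=9)
        meta = table.metadata
        m = table.cell_vectors[meta["tissue"] == "t1"].mean(0)
        table.cell_vectors[(meta["tissue"] == "t1").to_numpy()] = m
        table.cell_vectors[(meta["tissue"] == "t3").to_numpy()] = m
        df, _ = pf.tissue_similarity_matrix(table)
        assert np.isclose(df.loc["t1", "t3"], 1.0)

    def test_pearson_matches_numpy_corrcoef(self):
        table = _toy_table(seed=10)
        df, _ = pf.tissue_similarity_matrix(table)
        means = [
            table.cell_vectors[table.cells_matching({"tissue": t})].mean(0)
            for t in df.index
        ]
        assert np.allclose(df.values, np.corrcoef(np.array(means)), atol=1e-12)

    def test_planted_hierarchy_recovered_in_dendrogram(self):
        """Two tissues sharing a program merge before the unrelated one."""
        rng = np.random.default_rng(11)
        h = 8
        shared = rng.normal(size=h) * 3
        other = rng.normal(size=h) * 3
        n = 30
        tissues = ["x"] * n + ["y"] * n + ["z"] * n
        cv = np.vstack(
            [
                shared + 0.1 * rng.normal(size=(n, h)),
                shared + 0.12 * rng.normal(size=(n, h)),
                other + 0.1 * rng.normal(size=(n, h)),
            ]
        )
        table = EmbeddingTable(
            vectors=cv,
            cell_index=np.arange(3 * n),
            role=np.array(["g"] * 3 * n),
            metadata=pd.DataFrame({"tissue": tissues}),
            cell_vectors=cv,
            cell_ids=[str(i) for i in range(3 * n)],
            fields=["tissue"],
        )
        df, Z = pf.tissue_similarity_matrix(table)
        # first merge joins x and y (leaves 0 and 1)
        assert set(Z[0, :2].astype(int)) == {0, 1}


class TestGeneNetwork:
    def _embeddings(self, seed=0, n=50, h=10):
        rng = np.random.default_rng(seed)
        return {f"g{i:02d}": rng.normal(size=h) for i in range(n)}

    def test_edges_match_brute_force_pair_scan(self):
        emb = self._embeddings()
        net = pf.build_gene_network(emb, quantile=0.9)
        genes = sorted(emb)
        expected = {
            frozenset((a, b))
            for a, b in itertools.combinations(genes, 2)
            if pf.cosine_similarity(emb[a], emb[b]) > net.tau
        }
        got = {frozenset(e) for e in net.graph.edges}
        assert got == expected

    def test_tau_one_gives_empty_graph(self):
        net = pf.build_gene_network(self._embeddings(1), tau=1.0)
        assert net.graph.number_of_edges() == 0

    def test_tau_minus_one_gives_complete_graph(self):
        net = pf.build_gene_network(self._embeddings(2, n=20), tau=-1.0)
        assert all(d == 19 for _, d in net.graph.degree())

    def test_bad_quantile_rejected(self):
        with pytest.raises(pf.ParameterError):
            pf.build_gene_network(self._embeddings(3), quantile=1.5)

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        net = pf.build_gene_network(self._embeddings(4, n=15), quantile=0.8)
        p = tmp_path / "net.graphml"
        net.write_graphml(p)
        back = nx.read_graphml(p)
        assert set(back.nodes) == set(net.graph.nodes)
        assert back.number_of_edges() == net.graph.number_of_edges()


class TestPowerLaw:
    def test_mle_recovers_generating_exponent(self):
        rng = np.random.default_rng(42)
        degrees = sample_discrete_power_law(2.5, 1, 10_000, rng)
        fit = fit_power_law(degrees)
        assert 2.35 <= fit.alpha <= 2.65
        assert fit.xmin >= 1

    def test_estimate_invariant_to_order(self):
        rng = np.random.default_rng(1)
        degrees = sample_discrete_power_law(2.2, 1, 2000, rng)
        f1 = fit_power_law(degrees)
        f2 = fit_power_law(degrees[::-1].copy())
        assert f1.alpha == f2.alpha
        assert f1.xmin == f2.xmin

    def test_tiny_sample_warns_but_fits(self):
        with pytest.warns(UserWarning, match="unstable"):
            fit = fit_power_law(np.array([1, 1, 1, 2]))
        assert fit.alpha > 1

    def test_degenerate_all_equal_rejected(self):
        with pytest.raises(pf.ParameterError, match="degenerate"):
            fit_power_law(np.full(100, 3))

    def test_zero_degrees_dropped(self):
        rng = np.random.default_rng(2)
        degrees = np.concatenate(
            [sample_discrete_power_law(2.5, 1, 1000, rng), np.zeros(100, dtype=int)]
        )
        fit = fit_power_law(degrees)
        assert fit.n_tail <= 1000


class TestDendrogram:
    def test_two_genes_single_merge_at_their_distance(self):
        emb = {"a": np.array([1.0, 0.0]), "b": np.array([1.0, 1.0])}
        Z, leaves, nwk = pf.gene_dendrogram(emb)
        assert Z.shape == (1, 4)
        d = 1 - pf.cosine_similarity(emb["a"], emb["b"])
        assert np.isclose(Z[0, 2], d, atol=1e-12)
        assert leaves == ["a", "b"]

    def test_leaves_are_input_genes_exactly_once(self):
        rng = np.random.default_rng(3)
        emb = {f"g{i}": rng.normal(size=5) for i in range(9)}
        Z, leaves, nwk = pf.gene_dendrogram(emb)
        import re

        found = sorted(re.findall(r"g\d", nwk))
        assert found == sorted(emb)

    def test_merge_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(4)
        emb = {f"g{i}": rng.normal(size=6) for i in range(8)}
        Z, leaves, _ = pf.gene_dendrogram(emb)
        X = np.array([emb[g] for g in sorted(emb)])
        from scipy.spatial.distance import pdist

        Z_oracle = scipy_linkage(pdist(X, "cosine"), method="average")
        assert np.allclose(Z[:, 2], Z_oracle[:, 2], atol=1e-12)


class TestCompareNetworks:
    def _net(self, emb, tau):
        return pf.build_gene_network(emb, tau=tau)

    def test_identical_networks_zero_deltas_equal_alphas(self):
        rng = np.random.default_rng(5)
        # heavy-tailed degrees: star-ish structure via low threshold
        emb = {f"g{i:03d}": rng.normal(size=4) for i in range(120)}
        net = self._net(emb, tau=0.5)
        rep = pf.compare_networks(net, net)
        assert (rep["degree_delta"] == 0).all()
        if rep["fit_a"] is not None:
            assert rep["alpha_delta"] == 0.0

    def test_added_edges_top_the_delta_ranking(self):
        rng = np.random.default_rng(6)
        emb = {f"g{i:02d}": rng.normal(size=4) for i in range(30)}
        net_a = self._net(emb, tau=0.6)
        net_b = pf.GeneNetwork(graph=net_a.graph.copy(), tau=net_a.tau)
        target = "g00"
        others = [g for g in net_b.nodes if g != target][:5]
        for o in others:
            net_b.graph.add_edge(target, o)
        rep = pf.compare_networks(net_a, net_b)
        assert rep["top_changed_by_degree"].index[0] == target

    def test_disjoint_node_sets_rejected(self):
        rng = np.random.default_rng(7)
        e1 = {f"a{i}": rng.normal(size=3) for i in range(5)}
        e2 = {f"b{i}": rng.normal(size=3) for i in range(5)}
        with pytest.raises(pf.ValidationError):
            pf.compare_networks(self._net(e1, 0.0), self._net(e2, 0.0))


class TestPolyfunctionality:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_two_mode_gene_detected_one_mode_rejected(self, seed):
        """Planted two-mode embedding clouds yield exactly 2 clusters and a
        polyfunctional flag; unimodal clouds yield 1, across 5 seeds."""
        table2, _ = pf.generate_mode_embeddings(
            n_cells=200, n_modes=2, hidden=16, separation=6.0, seed=seed
        )
        res2 = pf.polyfunctionality(table2, "GPOLY", "ct1", seed=seed)
        assert res2.n_clusters == 2
        assert res2.polyfunctional

        table1, _ = pf.generate_mode_embeddings(
            n_cells=200, n_modes=1, hidden=16, separation=6.0, seed=seed
        )
        res1 = pf.polyfunctionality(table1, "GPOLY", "ct1", seed=seed)
        assert res1.n_clusters == 1
        assert not res1.polyfunctional

    def test_identical_embeddings_give_single_cluster(self):
        table, _ = pf.generate_mode_embeddings(
            n_cells=80, n_modes=1, hidden=8, separation=0.0, seed=0
        )
        rows = table.rows_for("GPOLY")
        table.vectors[rows] = 1.0
        res = pf.polyfunctionality(table, "GPOLY", "ct1")
        assert res.n_clusters == 1
        assert not res.polyfunctional

    def test_insufficient_cells_rejected(self):
        table, _ = pf.generate_mode_embeddings(
            n_cells=20, n_modes=2, hidden=8, separation=5.0, seed=0
        )
        with pytest.raises(pf.SupportError):
            pf.polyfunctionality(table, "GPOLY", "ct1", min_cells=50)

    def test_small_cluster_merging(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 4))
        labels = np.zeros(100, dtype=int)
        labels[:3] = 1  # 3% cluster must be absorbed
        merged = _merge_small_clusters(X, labels, min_frac=0.05)
        assert len(np.unique(merged)) == 1
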