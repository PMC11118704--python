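"""Contextualized-embedding extraction and downstream analytics.

The encoder's final-norm hidden states on *uncorrupted* cells are the
contextualized embeddings: one h-vector per non-PAD slot per cell, each
conditioned on the whole cell.  Averaging an entity's vectors over all cells
sharing a phenotype context yields context embeddings, which drive every
analysis here: phenotype-gene cosine similarity and "universal" gene
rankings, differentially embedded genes (DEGs — genes whose context
embeddings diverge across values of a field), tissue Pearson-correlation
matrices with average-linkage dendrograms, similarity-threshold gene
networks with degree/power-law summaries, gene dendrograms, and
polyfunctionality (a gene whose per-cell embeddings form >=2 well-separated
clusters within one cell type).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .corpus import TokenizedCells
from .errors import ParameterError, SchemaError, SupportError, ValidationError
from .model import ModelConfig, ParameterSet, forward
from .powerlaw import PowerLawFit, fit_power_law

logger = logging.getLogger(__name__)


# -- embedding extraction ----------------------------------------------------


@dataclass
class EmbeddingTable:
    """Last-layer states per (cell, non-PAD slot), with cell metadata joined.

    ``role`` labels each row with the slot's entity: the phenotype field
    name for phenotype slots, the gene id for gene slots.  ``cell_vectors``
    is the per-cell mean over that cell's non-PAD slots.
    """

    vectors: np.ndarray          # (n_rows, h)
    cell_index: np.ndarray       # (n_rows,) int, row into metadata
    role: np.ndarray             # (n_rows,) str
    metadata: pd.DataFrame       # one row per cell
    cell_vectors: np.ndarray     # (n_cells, h)
    cell_ids: list[str]
    fields: list[str]

    @property
    def n_rows(self) -> int:
        return self.vectors.shape[0]

    def cells_matching(self, context: dict[str, str] | None) -> np.ndarray:
        """Indices of cells whose metadata matches every (field, value) pair."""
        mask = np.ones(len(self.metadata), dtype=bool)
        for f, v in (context or {}).items():
            if f not in self.metadata.columns:
                raise SchemaError(f"unknown phenotype field {f!r}")
            mask &= self.metadata[f].to_numpy() == v
        return np.where(mask)[0]

    def rows_for(self, entity: str, cells: np.ndarray | None = None) -> np.ndarray:
        """Row indices for one entity (gene id or field name), optionally
        restricted to a cell subset."""
        sel = self.role == entity
        if cells is not None:
            sel &= np.isin(self.cell_index, cells)
        return np.where(sel)[0]

    def save_h5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("vectors", data=self.vectors)
            f.create_dataset("cell_index", data=self.cell_index)
            f.create_dataset("role", data=np.asarray(self.role, dtype="S"))
            f.create_dataset("cell_vectors", data=self.cell_vectors)
            f.create_dataset("cell_ids", data=np.asarray(self.cell_ids, dtype="S"))
            f.attrs["fields"] = list(self.fields)
            for c in self.metadata.columns:
                f.create_dataset(
                    f"metadata/{c}", data=self.metadata[c].astype(str).to_numpy(dtype="S")
                )

    @classmethod
    def load_h5(cls, path: str | Path) -> "EmbeddingTable":
        import h5py

        with h5py.File(path, "r") as f:
            meta = {
                c: [s.decode() for s in f[f"metadata/{c}"][:]]
                for c in f["metadata"].keys()
            }
            return cls(
                vectors=f["vectors"][:],
                cell_index=f["cell_index"][:],
                role=np.array([s.decode() for s in f["role"][:]]),
                metadata=pd.DataFrame(meta),
                cell_vectors=f["cell_vectors"][:],
                cell_ids=[s.decode() for s in f["cell_ids"][:]],
                fields=list(f.attrs["fields"]),
            )


def extract_embeddings(
    params: ParameterSet,
    model_cfg: ModelConfig,
    cells: TokenizedCells,
    batch_size: int = 128,
) -> EmbeddingTable:
    """Final-norm hidden states of uncorrupted cells, one row per non-PAD slot."""
    n = cells.n_cells
    F = cells.F
    roles = np.array(list(cells.vocab.fields) + list(cells.gene_slots))
    vec_chunks, cell_idx_chunks, role_chunks = [], [], []
    cell_vectors = np.zeros((n, model_cfg.hidden))
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        tok = cells.tokens[sl]
        pad = cells.pad_mask[sl]
        _, y, _ = forward(params, model_cfg, tok, pad)
        keep = ~pad
        for b in range(tok.shape[0]):
            rows = np.where(keep[b])[0]
            vec_chunks.append(y[b, rows])
            cell_idx_chunks.append(np.full(len(rows), start + b))
            role_chunks.append(roles[rows])
            cell_vectors[start + b] = y[b, rows].mean(axis=0)
    return EmbeddingTable(
        vectors=np.concatenate(vec_chunks),
        cell_index=np.concatenate(cell_idx_chunks),
        role=np.concatenate(role_chunks),
        metadata=cells.metadata.reset_index(drop=True),
        cell_vectors=cell_vectors,
        cell_ids=list(cells.cell_ids),
        fields=list(cells.vocab.fields),
    )


# -- context aggregation -----------------------------------------------------


@dataclass
class ContextEmbedding:
    """Mean embedding of one entity over all cells sharing a context."""

    entity: str
    context: tuple[str, ...]
    vector: np.ndarray
    n_cells: int
    low_support: bool = False


def aggregate_by_context(
    table: EmbeddingTable,
    entity: str,
    grouping_fields: list[str],
    min_support: int = 20,
) -> list[ContextEmbedding]:
    """One mean vector per observed combination of the grouping fields."""
    for f in grouping_fields:
        if f not in table.metadata.columns:
            raise SchemaError(f"unknown grouping field {f!r}")
    rows = table.rows_for(entity)
    if rows.size == 0:
        raise SchemaError(f"entity {entity!r} absent from the embedding table")
    ctx = table.metadata.iloc[table.cell_index[rows]][grouping_fields]
    out = []
    for key, grp in ctx.groupby(grouping_fields, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        idx = rows[ctx.index.get_indexer(grp.index)]
        out.append(
            ContextEmbedding(
                entity=entity,
                context=tuple(map(str, key)),
                vector=table.vectors[idx].mean(axis=0),
                n_cells=len(idx),
                low_support=len(idx) < min_support,
            )
        )
    return out


def entity_context_vector(
    table: EmbeddingTable, entity: str, context: dict[str, str] | None
) -> np.ndarray | None:
    """Mean embedding of an entity over cells matching a context, or None."""
    cells = table.cells_matching(context)
    rows = table.rows_for(entity, cells)
    if rows.size == 0:
        return None
    return table.vectors[rows].mean(axis=0)


def gene_context_embeddings(
    table: EmbeddingTable, context: dict[str, str] | None = None, min_cells: int = 1
) -> dict[str, np.ndarray]:
    """Mean embedding per gene over cells matching a phenotype context."""
    cells = table.cells_matching(context)
    sel = np.isin(table.cell_index, cells) & ~np.isin(table.role, table.fields)
    rows = np.where(sel)[0]
    out: dict[str, np.ndarray] = {}
    roles = table.role[rows]
    for g in np.unique(roles):
        idx = rows[roles == g]
        if len(idx) >= min_cells:
            out[str(g)] = table.vectors[idx].mean(axis=0)
    return out


# -- similarity primitives ---------------------------------------------------


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def embedding_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two context embeddings."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def gene_context_distance(
    table: EmbeddingTable, gene: str, context_a: dict[str, str], context_b: dict[str, str]
) -> float:
    va = entity_context_vector(table, gene, context_a)
    vb = entity_context_vector(table, gene, context_b)
    if va is None or vb is None:
        raise SupportError(f"gene {gene!r} unobserved in one of the contexts")
    return embedding_distance(va, vb)


# -- phenotype-gene similarity and DEGs -------------------------------------


def phenotype_gene_similarity(
    table: EmbeddingTable, field: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cosine similarity of each gene to a phenotype slot, per context value.

    For every value v of ``field``, the phenotype slot's context embedding
    and each gene's context embedding are computed over the cells with that
    value; their cosine similarity fills one column.  The "universal" score
    of a gene is the mean over values (missing contexts excluded); the
    minimum is reported alongside.  Returns (similarity matrix, ranking).
    """
    if field not in table.fields:
        raise SchemaError(f"unknown phenotype field {field!r}")
    values = sorted(table.metadata[field].unique())
    cols: dict[str, dict[str, float]] = {}
    for v in values:
        ctx = {field: v}
        pheno_vec = entity_context_vector(table, field, ctx)
        genes = gene_context_embeddings(table, ctx)
        cols[v] = {g: cosine_similarity(vec, pheno_vec) for g, vec in genes.items()}
    mat = pd.DataFrame(cols)
    ranking = pd.DataFrame(
        {
            "universal": mat.mean(axis=1, skipna=True),
            "min": mat.min(axis=1, skipna=True),
            "n_contexts": mat.notna().sum(axis=1),
        }
    ).sort_values("universal", ascending=False)
    return mat, ranking


def differential_embedding_score(vectors: list[np.ndarray] | np.ndarray) -> float:
    """Dispersion of one gene's context embeddings: 1 - mean pairwise cosine.

    0 for identical embeddings; up to 2 for antipodal ones.  Requires >=2
    contexts.
    """
    vecs = np.asarray(vectors, dtype=float)
    if vecs.shape[0] < 2:
        raise SupportError("need >=2 context embeddings")
    sims = [
        cosine_similarity(vecs[i], vecs[j])
        for i, j in itertools.combinations(range(vecs.shape[0]), 2)
    ]
    return float(1.0 - np.mean(sims))


def differential_embedding_scores(
    table: EmbeddingTable, field: str, min_cells: int = 1
) -> pd.Series:
    """DEG ranking: per-gene dispersion of context embeddings across a field's
    values, sorted descending.  Genes observed in <2 values are excluded."""
    if field not in table.fields:
        raise SchemaError(f"unknown phenotype field {field!r}")
    values = sorted(table.metadata[field].unique())
    per_value = [
        gene_context_embeddings(table, {field: v}, min_cells=min_cells) for v in values
    ]
    genes = set().union(*(d.keys() for d in per_value))
    scores = {}
    for g in sorted(genes):
        vecs = [d[g] for d in per_value if g in d]
        if len(vecs) >= 2:
            scores[g] = differential_embedding_score(vecs)
    return pd.Series(scores, name="deg_score").sort_values(ascending=False)


# -- tissue similarity -------------------------------------------------------


def tissue_similarity_matrix(
    table: EmbeddingTable, field: str = "tissue"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pearson correlation between per-tissue mean cell embeddings, plus an
    average-linkage dendrogram (scipy linkage on distance 1 - r)."""
    values = sorted(table.metadata[field].unique())
    if len(values) < 2:
        raise SupportError("need >=2 tissues")
    means = []
    for v in values:
        idx = table.cells_matching({field: v})
        if len(idx) < 2:
            logger.warning("tissue %r has <2 cells", v)
        means.append(table.cell_vectors[idx].mean(axis=0))
    M = np.asarray(means)
    corr = np.corrcoef(M)
    np.fill_diagonal(corr, 1.0)
    df = pd.DataFrame(corr, index=values, columns=values)
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    Z = linkage(dist, method="average")
    return df, Z


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, leaf_names)
    return str(tree).strip()


# -- gene networks -----------------------------------------------------------


@dataclass
class GeneNetwork:
    """Undirected similarity-threshold graph over genes."""

    graph: nx.Graph
    tau: float
    context: dict[str, str] | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def degree_sequence(self) -> np.ndarray:
        return np.array([d for _, d in self.graph.degree()])

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def build_gene_network(
    embeddings: dict[str, np.ndarray],
    tau: float | None = None,
    quantile: float = 0.95,
    context: dict[str, str] | None = None,
) -> GeneNetwork:
    """Connect gene pairs whose context-embedding cosine similarity exceeds
    a threshold, given absolutely (``tau``) or as a quantile of all pairwise
    similarities (default 0.95)."""
    genes = sorted(embeddings)
    if len(genes) < 2:
        raise SupportError("need >=2 genes to build a network")
    X = np.asarray([embeddings[g] for g in genes], dtype=float)
    sims = 1.0 - pdist(X, metric="cosine")
    if tau is None:
        if not 0.0 < quantile < 1.0:
            raise ParameterError("quantile must lie in (0, 1)")
        tau = float(np.quantile(sims, quantile))
    G = nx.Graph()
    G.add_nodes_from(genes)
    it = iter(sims)
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            s = next(it)
            if s > tau:
                G.add_edge(gi, gj, similarity=float(s))
    return GeneNetwork(graph=G, tau=float(tau), context=context)


def gene_dendrogram(
    embeddings: dict[str, np.ndarray],
) -> tuple[np.ndarray, list[str], str]:
    """Average-linkage agglomerative clustering on cosine distance.

    Returns (linkage matrix, leaf order, Newick string with gene ids)."""
    genes = sorted(embeddings)
    if len(genes) < 2:
        raise SupportError("need >=2 genes")
    X = np.asarray([embeddings[g] for g in genes], dtype=float)
    Z = linkage(pdist(X, metric="cosine"), method="average")
    return Z, genes, linkage_to_newick(Z, genes)


def compare_networks(
    net_a: GeneNetwork,
    net_b: GeneNetwork,
    embeddings_a: dict[str, np.ndarray] | None = None,
    embeddings_b: dict[str, np.ndarray] | None = None,
    top: int = 20,
) -> dict:
    """Contrast two context networks: power-law fits, per-gene degree change
    on the shared node set, and (optionally) per-gene embedding shift between
    the two contexts (1 - cosine of the gene's two context embeddings)."""
    shared = sorted(set(net_a.nodes) & set(net_b.nodes))
    if not shared:
        raise ValidationError("networks share no nodes")

    def _fit(net: GeneNetwork) -> PowerLawFit | None:
        degs = net.degree_sequence
        degs = degs[degs > 0]
        try:
            return fit_power_law(degs)
        except (ParameterError, SupportError) as e:
            logger.warning("power-law fit unavailable: %s", e)
            return None

    fit_a, fit_b = _fit(net_a), _fit(net_b)
    da, db = net_a.degrees(), net_b.degrees()
    delta = pd.Series({g: db[g] - da[g] for g in shared}, name="degree_delta")
    by_delta = delta.reindex(delta.abs().sort_values(ascending=False).index)
    report = {
        "fit_a": fit_a,
        "fit_b": fit_b,
        "alpha_delta": (
            fit_b.alpha - fit_a.alpha if fit_a is not None and fit_b is not None else None
        ),
        "degree_delta": delta,
        "top_changed_by_degree": by_delta.head(top),
    }
    if embeddings_a is not None and embeddings_b is not None:
        shift = {
            g: 1.0 - cosine_similarity(embeddings_a[g], embeddings_b[g])
            for g in shared
            if g in embeddings_a and g in embeddings_b
        }
        s = pd.Series(shift, name="embedding_shift").sort_values(ascending=False)
        report["top_changed_by_embedding"] = s.head(top)
    return report


# -- polyfunctionality -------------------------------------------------------


@dataclass
class PolyfunctionalityResult:
    gene: str
    cell_type: str
    labels: np.ndarray
    n_clusters: int
    silhouette: float | None
    polyfunctional: bool
    cluster_partners: dict[int, list[str]] = dc_field(default_factory=dict)
    cell_indices: np.ndarray | None = None


def _leiden_labels(
    X: np.ndarray, k_neighbors: int, resolution: float, seed: int
) -> np.ndarray:
    import igraph as ig
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    n = X.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(X)
    _, nbrs = nn.kneighbors(X)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in nbrs[i, 1:]}
    g = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def _merge_small_clusters(
    X: np.ndarray, labels: np.ndarray, min_frac: float
) -> np.ndarray:
    """Fold clusters below ``min_frac`` of cells into the cluster with the
    nearest (cosine) centroid."""
    labels = labels.copy()
    n = len(labels)
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) <= 1:
            break
        small = uniq[counts < min_frac * n]
        if small.size == 0:
            break
        centroids = {u: X[labels == u].mean(axis=0) for u in uniq}
        s = small[np.argmin([counts[list(uniq).index(u)] for u in small])]
        others = [u for u in uniq if u != s]
        target = max(
            others, key=lambda u: cosine_similarity(centroids[s], centroids[u])
        )
        labels[labels == s] = target
    # relabel contiguously
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _merge_path_best(X: np.ndarray, labels: np.ndarray):
    """Greedily merge the two most-similar (cosine centroid) clusters down
    to 2 and return the partition with the highest cosine silhouette along
    the path, with that silhouette.  Collapses community-detection
    over-partitioning to the best-separated coarsening."""
    from sklearn.metrics import silhouette_score

    labels = labels.copy()
    best_labels, best_sil = labels.copy(), silhouette_score(
        X, labels, metric="cosine"
    )
    while len(np.unique(labels)) > 2:
        uniq = np.unique(labels)
        centroids = {u: X[labels == u].mean(axis=0) for u in uniq}
        pair, pair_sim = None, -np.inf
        for i, a in enumerate(uniq):
            for b in uniq[i + 1 :]:
                s = cosine_similarity(centroids[a], centroids[b])
                if s > pair_sim:
                    pair, pair_sim = (a, b), s
        labels[labels == pair[1]] = pair[0]
        sil = silhouette_score(X, labels, metric="cosine")
        if sil > best_sil:
            best_labels, best_sil = labels.copy(), sil
    _, best_labels = np.unique(best_labels, return_inverse=True)
    return best_labels, float(best_sil)


def _candidate_partition(
    X: np.ndarray, k_neighbors: int, resolution: float, min_frac: float, seed: int
):
    lab = _merge_small_clusters(
        X, _leiden_labels(X, k_neighbors, resolution, seed), min_frac
    )
    if len(np.unique(lab)) < 2:
        return np.zeros(len(lab), dtype=int), 0.0
    return _merge_path_best(X, lab)


def _cluster_stability(
    X: np.ndarray,
    ref_labels: np.ndarray,
    k_neighbors: int,
    resolution: float,
    min_frac: float,
    seed: int,
    n_replicates: int = 3,
    subsample: float = 0.8,
) -> float:
    """Median adjusted Rand index between the reference partition and
    partitions recomputed on 80% subsamples.  Genuine modes reproduce
    almost exactly; the spatial patches kNN community detection carves out
    of a unimodal cloud have arbitrary boundaries and do not."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed + 1000)
    n = len(ref_labels)
    aris = []
    for _ in range(n_replicates):
        idx = np.sort(rng.choice(n, int(subsample * n), replace=False))
        sub_lab, _ = _candidate_partition(
            X[idx], k_neighbors, resolution, min_frac, seed
        )
        aris.append(adjusted_rand_score(ref_labels[idx], sub_lab))
    return float(np.median(aris))


def polyfunctionality(
    table: EmbeddingTable,
    gene: str,
    cell_type: str,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    cell_type_field: str = "cell_type",
    min_cells: int = 50,
    min_cluster_frac: float = 0.05,
    silhouette_floor: float = 0.1,
    stability_floor: float = 0.5,
    seed: int = 0,
    n_partner_genes: int = 10,
) -> PolyfunctionalityResult:
    """Cluster one gene's per-cell embeddings within a cell type.

    A k-nearest-neighbour graph (cosine metric) over the gene's per-cell
    contextual embeddings is partitioned by Leiden community detection at
    the given resolution; clusters below ``min_cluster_frac`` of the cells
    merge into the nearest cluster, then the over-partitioning is coarsened
    to the merge-path partition with the best cosine silhouette.  Structure
    is accepted only if that silhouette reaches ``silhouette_floor`` AND
    the partition is reproducible on 80% subsamples (median adjusted Rand
    index >= ``stability_floor``) — kNN communities of a unimodal cloud
    pass neither test reliably.  The gene is flagged polyfunctional at >=2
    accepted clusters.  For each cluster, the genes whose within-cluster
    context embeddings are most cosine-similar to the cluster centroid are
    reported as partners.
    """
    cells = table.cells_matching({cell_type_field: cell_type})
    rows = table.rows_for(gene, cells)
    if rows.size < min_cells:
        raise SupportError(
            f"gene {gene!r} has embeddings in only {rows.size} cells of "
            f"{cell_type!r} (need >= {min_cells})"
        )
    X = table.vectors[rows]
    member_cells = table.cell_index[rows]

    if np.allclose(X.std(axis=0), 0):
        labels = np.zeros(len(rows), dtype=int)
    else:
        best_labels, obs_sil = _candidate_partition(
            X, k_neighbors, resolution, min_cluster_frac, seed
        )
        labels = np.zeros(len(rows), dtype=int)
        if len(np.unique(best_labels)) >= 2 and obs_sil >= silhouette_floor:
            # genuine modes must also be reproducible under subsampling
            stability = _cluster_stability(
                X, best_labels, k_neighbors, resolution, min_cluster_frac, seed
            )
            if stability >= stability_floor:
                labels = best_labels
    n_clusters = int(labels.max()) + 1

    sil = None
    if n_clusters >= 2:
        from sklearn.metrics import silhouette_score

        sil = float(silhouette_score(X, labels, metric="cosine"))
    poly = n_clusters >= 2 and sil is not None and sil >= silhouette_floor

    partners: dict[int, list[str]] = {}
    for c in range(n_clusters):
        centroid = X[labels == c].mean(axis=0)
        cluster_cells = np.unique(member_cells[labels == c])
        sel = np.isin(table.cell_index, cluster_cells) & ~np.isin(
            table.role, table.fields
        )
        rws = np.where(sel)[0]
        roles = table.role[rws]
        sims = {}
        for g in np.unique(roles):
            if g == gene:
                continue
            vec = table.vectors[rws[roles == g]].mean(axis=0)
            try:
                sims[str(g)] = cosine_similarity(vec, centroid)
            except ValidationError:
                continue
        partners[c] = sorted(sims, key=sims.get, reverse=True)[:n_partner_genes]

    return PolyfunctionalityResult(
        gene=gene,
        cell_type=cell_type,
        labels=labels,
        n_clusters=n_clusters,
        silhouette=sil,
        polyfunctional=bool(poly),
        cluster_partners=partners,
        cell_indices=member_cells,
    )
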