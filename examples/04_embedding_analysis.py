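"""Contextualized embeddings: tissue similarity, universal genes, DEGs.

Extracts last-layer embeddings from a trained model, then runs the
embedding analytics: Pearson tissue-similarity matrix with a dendrogram,
genes most cosine-similar to the tissue phenotype across all tissues
("universal" genes), and differentially embedded genes (DEGs) — genes whose
context embeddings diverge most between tissues.
"""

import numpy as np

import phenoformer as pf

atlas, truth = pf.generate_atlas(pf.SyntheticConfig(seed=1, n_cells=800, n_genes=300))
bundle = pf.preprocess_and_tokenize(atlas, T=64, B=8)
train_cells, val_cells = pf.train_validation_split(bundle.cells, seed=0)
model_cfg = pf.ModelConfig.for_cells(bundle.cells, dropout=0.0)
params, _ = pf.pretrain(
    train_cells, model_cfg, pf.TrainConfig(learning_rate=1e-3, epochs=4, seed=0)
)

table = pf.extract_embeddings(params, model_cfg, val_cells)
print(f"embedding table: {table.n_rows} rows (one per non-PAD slot per cell)")

corr_df, Z = pf.tissue_similarity_matrix(table)
print("\ntissue Pearson correlation matrix:")
print(corr_df.round(3))
print("dendrogram (Newick):", pf.linkage_to_newick(Z, list(corr_df.index)))

_, ranking = pf.phenotype_gene_similarity(table, "tissue")
markers = set(g for gs in truth.markers["tissue"].values() for g in gs)
print("\ntop-5 universally tissue-similar genes (| = planted marker):")
for g in ranking.index[:5]:
    flag = "|planted" if g in markers else ""
    print(f"  {g} universal={ranking.loc[g, 'universal']:.3f} {flag}")

degs = pf.differential_embedding_scores(table, "tissue")
print("\ntop-5 differentially embedded genes across tissues:")
print(degs.head(5).round(4).to_string())
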