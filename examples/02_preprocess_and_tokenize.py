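"""Raw counts -> normalized, HVG-ranked, binned token sequences.

Cells are library-scaled, log1p-transformed and dispersion-normalized; the
top-T most variable genes define fixed gene slots; values below the
expressed threshold become PAD, the rest map to B equal-width bins.
"""

import numpy as np

import phenoformer as pf

atlas, truth = pf.generate_atlas(pf.SyntheticConfig(seed=1, n_cells=500, n_genes=300))
bundle = pf.preprocess_and_tokenize(atlas, T=64, B=8)

cells = bundle.cells
print(f"vocabulary size: {bundle.vocab.size} "
      f"(2 specials + {bundle.vocab.B} bins + phenotype categories)")
print(f"sequence length: {cells.seq_len} = {cells.F} phenotype + {cells.T} gene slots")
print(f"threshold: {bundle.spec.threshold}  "
      f"bin edges: {np.round(bundle.spec.bin_edges, 2)}")
print(f"PAD fraction in gene slots: {cells.pad_mask[:, cells.F:].mean():.2f} "
      "(genes below threshold in a given cell)")

planted = set(truth.gene_programs)
frac = np.mean([g in planted for g in bundle.ranking.retained])
print(f"fraction of top-{cells.T} HVGs that are planted program genes: {frac:.2f}")

corr = pf.corrupt(cells, pf.MaskingPolicy(), np.random.default_rng(0))
print(f"masked phenotype slots: {corr.masked[:, :cells.F].mean():.3f} (target 0.50)")
ok = ~cells.pad_mask[:, cells.F:]
print(f"masked gene slots:      {corr.masked[:, cells.F:][ok].mean():.3f} (target 0.15)")
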