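import numpy as np
import pandas as pd
import pytest

import phenoformer as pf


@pytest.fixture(scope="session")
def small_atlas():
    """A 400-cell synthetic atlas with planted programs."""
    cfg = pf.SyntheticConfig(seed=11, n_cells=400, n_genes=300)
    return pf.generate_atlas(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_atlas):
    atlas, _ = small_atlas
    return pf.preprocess_and_tokenize(atlas, T=32, B=8)


@pytest.fixture(scope="session")
def tiny_cells():
    """A hand-sized tokenized batch over a 2-field schema, for model tests."""
    schema = {"sex": ["F", "M"], "tissue": ["a", "b", "c"]}
    vocab = pf.build_vocabulary(schema, B=4)
    F, T, n = 2, 5, 6
    rng = np.random.default_rng(0)
    tokens = np.zeros((n, F + T), dtype=np.int64)
    tokens[:, 0] = rng.integers(0, 2, n) + vocab.field_offsets["sex"]
    tokens[:, 1] = rng.integers(0, 3, n) + vocab.field_offsets["tissue"]
    gene = rng.integers(-1, 4, (n, T))
    tokens[:, F:] = np.where(gene < 0, pf.PAD_ID, gene + vocab.bin_offset)
    meta = pd.DataFrame({"sex": ["F"] * n, "tissue": ["a", "b", "c"] * 2})
    return pf.TokenizedCells(
        tokens=tokens,
        pad_mask=tokens == pf.PAD_ID,
        vocab=vocab,
        gene_slots=[f"g{i}" for i in range(T)],
        cell_ids=[f"c{i}" for i in range(n)],
        metadata=meta,
    )


@pytest.fixture(scope="session")
def trained_pipeline():
    """Desk-scale end-to-end run shared by the slower tests: synthetic atlas
    (2,000 cells x 300 genes) -> preprocessing (T=64, B=8) -> reference-model
    training -> embeddings.  Session-scoped because training dominates the
    suite's runtime."""
    cfg = pf.SyntheticConfig(seed=7)
    atlas, truth = pf.generate_atlas(cfg)
    bundle = pf.preprocess_and_tokenize(atlas, T=64, B=8)
    train_cells, val_cells = pf.train_validation_split(bundle.cells, seed=0)
    model_cfg = pf.ModelConfig.for_cells(bundle.cells, dropout=0.0)
    train_cfg = pf.TrainConfig(learning_rate=1e-3, epochs=12, seed=0)
    params, history = pf.pretrain(train_cells, model_cfg, train_cfg)
    return {
        "atlas": atlas,
        "truth": truth,
        "bundle": bundle,
        "train_cells": train_cells,
        "val_cells": val_cells,
        "model_cfg": model_cfg,
        "train_cfg": train_cfg,
        "params": params,
        "history": history,
    }


@pytest.fixture(scope="session")
def trained_embeddings(trained_pipeline):
    """Embedding table of the held-out cells from the trained model."""
    return pf.extract_embeddings(
        trained_pipeline["params"],
        trained_pipeline["model_cfg"],
        trained_pipeline["val_cells"],
    )
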