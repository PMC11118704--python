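"""End-to-end convenience: raw matrix -> tokenized corpus -> trained model.

These wrappers chain the module-level operations with their defaults so an
analysis can go from counts to embeddings in a few lines; every step remains
individually accessible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import ExpressionMatrix
from .corpus import TokenizedCells, Vocabulary, build_vocabulary, tokenize_matrix
from .model import ModelConfig, ParameterSet
from .preprocess import (
    BinningSpec,
    GeneRanking,
    build_binning_spec,
    detect_threshold,
    normalize_expression,
    rank_hvg,
)
from .train import TrainConfig, pretrain, train_validation_split


@dataclass
class ProcessedBundle:
    """Everything the tokenizer produced, ready for training or inference."""

    cells: TokenizedCells
    ranking: GeneRanking
    spec: BinningSpec
    vocab: Vocabulary

    def save(self, directory) -> None:
        """Write the tokenized corpus (parquet) plus a JSON sidecar with the
        binning spec and HVG ranking."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells.to_parquet(directory / "corpus.parquet")
        sidecar = {
            "binning": {
                "threshold": self.spec.threshold,
                "B": self.spec.B,
                "bin_edges": self.spec.bin_edges.tolist(),
            },
            "ranking": {
                "ordered_genes": self.ranking.ordered_genes,
                "variability_score": self.ranking.variability_score.tolist(),
                "T": self.ranking.T,
            },
        }
        (directory / "processing.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, directory) -> "ProcessedBundle":
        import json
        from pathlib import Path

        import numpy as np

        directory = Path(directory)
        cells = TokenizedCells.from_parquet(directory / "corpus.parquet")
        sidecar = json.loads((directory / "processing.json").read_text())
        spec = BinningSpec(
            threshold=sidecar["binning"]["threshold"],
            B=sidecar["binning"]["B"],
            bin_edges=np.asarray(sidecar["binning"]["bin_edges"]),
        )
        ranking = GeneRanking(
            ordered_genes=sidecar["ranking"]["ordered_genes"],
            variability_score=np.asarray(sidecar["ranking"]["variability_score"]),
            T=sidecar["ranking"]["T"],
        )
        return cls(cells=cells, ranking=ranking, spec=spec, vocab=cells.vocab)


def preprocess_and_tokenize(
    raw: ExpressionMatrix,
    T: int,
    B: int = 10,
    threshold: float | str = "auto",
    target_total: float | None = None,
) -> ProcessedBundle:
    """normalize -> rank HVGs -> detect/set threshold -> bin -> tokenize.

    HVGs are ranked on the library-scaled log values (where variance/mean is
    informative); binning operates on the fully normalized scale.
    """
    from .preprocess import dispersion_scale, library_log_normalize

    logged = library_log_normalize(raw, target_total=target_total)
    ranking = rank_hvg(logged, T=T)
    norm = dispersion_scale(logged)
    thr = detect_threshold(norm) if threshold == "auto" else float(threshold)
    spec = build_binning_spec(norm, threshold=thr, B=B)
    vocab = build_vocabulary(raw.schema, B=B)
    cells = tokenize_matrix(norm, ranking, spec, vocab)
    return ProcessedBundle(cells=cells, ranking=ranking, spec=spec, vocab=vocab)


def train_reference_model(
    bundle: ProcessedBundle,
    train_cfg: TrainConfig,
    model_overrides: dict | None = None,
) -> tuple[ParameterSet, ModelConfig, list[float], TokenizedCells, TokenizedCells]:
    """Split 90/10 stratified by cell type, pretrain on the training split.

    Returns (params, model config, loss history, train cells, heldout cells).
    """
    cells_train, cells_val = train_validation_split(
        bundle.cells, seed=train_cfg.seed
    )
    model_cfg = ModelConfig.for_cells(bundle.cells, **(model_overrides or {}))
    params, history = pretrain(cells_train, model_cfg, train_cfg)
    return params, model_cfg, history, cells_train, cells_val
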