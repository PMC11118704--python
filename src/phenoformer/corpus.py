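"""Unified vocabulary, cell tokenization, masking and soft labels.

A cell becomes a fixed-length token sequence ``[p_1..p_F, g_1..g_T]``: F
phenotype tokens (one per categorical field, e.g. sex, age, tissue, cell
type) followed by T gene slots ordered by highly-variable-gene rank.  Gene
slot ``i`` always refers to the same gene — position, not order of
appearance, identifies the gene — and carries the gene's expression-bin
token, or PAD when the gene is below the expressed threshold in that cell.

Masked-language-model corruption replaces tokens with MASK at different
rates for the two modalities (phenotypes are fewer, so they are masked more
aggressively: 50% vs 15% by default); PAD slots are never masked and never
contribute to the loss.  Targets are soft labels: probability 1-r on the
true token and r/(n-1) spread over the other legal tokens of the slot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ExpressionMatrix, Schema
from .errors import ParameterError, SchemaError, ValidationError
from .preprocess import NON_EXPRESSED, BinningSpec, GeneRanking, bin_expression

PAD_ID: int = 0
MASK_ID: int = 1

#: position-class name for gene slots in ``Vocabulary.legal_sets``
GENE_CLASS = "__gene__"


@dataclass
class Vocabulary:
    """Contiguous token-id layout over bins, phenotype categories and specials.

    Layout: ``[PAD, MASK, bin_0..bin_{B-1}, field_1 categories..., field_2
    categories..., ...]`` with fields in schema order and categories in
    declared order — fully deterministic for a given schema and B.
    """

    B: int
    schema: Schema
    bin_offset: int = 2
    field_offsets: dict[str, int] = dc_field(default_factory=dict)
    size: int = 0

    def __post_init__(self) -> None:
        if not self.schema:
            raise SchemaError("phenotype schema must be non-empty")
        if self.B < 2:
            raise ParameterError("need at least 2 bins")
        offset = self.bin_offset + self.B
        self.field_offsets = {}
        for f, cats in self.schema.items():
            if len(set(cats)) != len(cats):
                raise SchemaError(f"duplicate category in field {f!r}")
            self.field_offsets[f] = offset
            offset += len(cats)
        self.size = offset

    # -- encoding -----------------------------------------------------------
    def bin_token(self, b: int) -> int:
        if not 0 <= b < self.B:
            raise ParameterError(f"bin {b} outside [0, {self.B})")
        return self.bin_offset + b

    def pheno_token(self, field: str, category: str) -> int:
        if field not in self.schema:
            raise SchemaError(f"unknown phenotype field {field!r}")
        try:
            return self.field_offsets[field] + self.schema[field].index(category)
        except ValueError:
            raise SchemaError(
                f"unknown category {category!r} for field {field!r}"
            ) from None

    def decode(self, token_id: int) -> str:
        if token_id == PAD_ID:
            return "<PAD>"
        if token_id == MASK_ID:
            return "<MASK>"
        if self.bin_offset <= token_id < self.bin_offset + self.B:
            return f"bin_{token_id - self.bin_offset}"
        for f, cats in self.schema.items():
            off = self.field_offsets[f]
            if off <= token_id < off + len(cats):
                return cats[token_id - off]
        raise ParameterError(f"token id {token_id} outside vocabulary")

    # -- legal sets ---------------------------------------------------------
    @property
    def legal_sets(self) -> dict[str, np.ndarray]:
        sets = {GENE_CLASS: np.arange(self.bin_offset, self.bin_offset + self.B)}
        for f, cats in self.schema.items():
            off = self.field_offsets[f]
            sets[f] = np.arange(off, off + len(cats))
        return sets

    @property
    def fields(self) -> list[str]:
        return list(self.schema)

    @property
    def F(self) -> int:
        return len(self.schema)

    def to_json(self) -> str:
        return json.dumps({"B": self.B, "schema": self.schema})

    @classmethod
    def from_json(cls, s: str) -> "Vocabulary":
        d = json.loads(s)
        return cls(B=d["B"], schema=d["schema"])


def build_vocabulary(phenotype_schema: Schema, B: int) -> Vocabulary:
    return Vocabulary(B=B, schema=dict(phenotype_schema))


# ---------------------------------------------------------------------------


@dataclass
class TokenizedCells:
    """A batch of fixed-length token sequences [p_1..p_F, g_1..g_T].

    ``tokens`` is (n_cells, F+T); ``pad_mask`` is True where a gene slot is
    PAD (gene below threshold).  Phenotype slots are never PAD.  Slot F+i
    permanently identifies the HVG of rank i.
    """

    tokens: np.ndarray
    pad_mask: np.ndarray
    vocab: Vocabulary
    gene_slots: list[str]          # gene id per gene slot, HVG-rank order
    cell_ids: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        n, S = self.tokens.shape
        if S != self.F + self.T:
            raise ValidationError("sequence length must be F+T")
        if self.pad_mask[:, : self.F].any():
            raise ValidationError("phenotype slots can never be PAD")

    @property
    def F(self) -> int:
        return self.vocab.F

    @property
    def T(self) -> int:
        return len(self.gene_slots)

    @property
    def n_cells(self) -> int:
        return self.tokens.shape[0]

    @property
    def seq_len(self) -> int:
        return self.tokens.shape[1]

    def slot_classes(self) -> list[str]:
        """Position-class label per slot: field name or GENE_CLASS."""
        return list(self.vocab.fields) + [GENE_CLASS] * self.T

    def subset(self, idx: np.ndarray) -> "TokenizedCells":
        idx = np.asarray(idx)
        return TokenizedCells(
            tokens=self.tokens[idx],
            pad_mask=self.pad_mask[idx],
            vocab=self.vocab,
            gene_slots=self.gene_slots,
            cell_ids=[self.cell_ids[i] for i in idx],
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
        )

    # -- serialization (columnar parquet + JSON sidecar) --------------------
    def to_parquet(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "tokens": list(self.tokens),
                "pad_mask": list(self.pad_mask),
            }
        )
        df = pd.concat([df, self.metadata.reset_index(drop=True)], axis=1)
        df.to_parquet(path, compression="zstd")
        sidecar = {"vocab": json.loads(self.vocab.to_json()), "gene_slots": self.gene_slots}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_parquet(cls, path: str | Path) -> "TokenizedCells":
        path = Path(path)
        df = pd.read_parquet(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        vocab = Vocabulary(B=sidecar["vocab"]["B"], schema=sidecar["vocab"]["schema"])
        meta_cols = [c for c in df.columns if c not in ("cell_id", "tokens", "pad_mask")]
        return cls(
            tokens=np.stack(df["tokens"].to_numpy()),
            pad_mask=np.stack(df["pad_mask"].to_numpy()),
            vocab=vocab,
            gene_slots=sidecar["gene_slots"],
            cell_ids=df["cell_id"].tolist(),
            metadata=df[meta_cols].copy(),
        )


def tokenize_cell(
    cell_values: dict[str, float] | pd.Series,
    phenotypes: dict[str, str] | pd.Series,
    ranking: GeneRanking,
    spec: BinningSpec,
    vocab: Vocabulary,
) -> tuple[np.ndarray, np.ndarray]:
    """Tokenize one cell; returns (tokens, pad_mask) of length F+T."""
    retained = ranking.retained
    values = np.array([float(cell_values[g]) for g in retained])
    bins = bin_expression(values, spec)
    gene_tokens = np.where(bins == NON_EXPRESSED, PAD_ID, bins + vocab.bin_offset)
    pheno_tokens = np.array(
        [vocab.pheno_token(f, str(phenotypes[f])) for f in vocab.fields]
    )
    tokens = np.concatenate([pheno_tokens, gene_tokens]).astype(np.int64)
    pad_mask = tokens == PAD_ID
    return tokens, pad_mask


def tokenize_matrix(
    matrix: ExpressionMatrix,
    ranking: GeneRanking,
    spec: BinningSpec,
    vocab: Vocabulary,
) -> TokenizedCells:
    """Tokenize every cell of a normalized expression matrix (vectorized)."""
    cols = [matrix.gene_index(g) for g in ranking.retained]
    values = matrix.dense()[:, cols]
    bins = bin_expression(values, spec)
    gene_tokens = np.where(bins == NON_EXPRESSED, PAD_ID, bins + vocab.bin_offset)
    pheno_tokens = np.column_stack(
        [
            matrix.phenotypes[f].astype(str).map(
                lambda c, f=f: vocab.pheno_token(f, c)).to_numpy()
            for f in vocab.fields
        ]
    )
    tokens = np.concatenate([pheno_tokens, gene_tokens], axis=1).astype(np.int64)
    return TokenizedCells(
        tokens=tokens,
        pad_mask=tokens == PAD_ID,
        vocab=vocab,
        gene_slots=list(ranking.retained),
        cell_ids=list(matrix.cell_ids),
        metadata=matrix.phenotypes.astype(str).reset_index(drop=True),
    )


# ---------------------------------------------------------------------------


@dataclass
class MaskingPolicy:
    """Bernoulli masking rates per modality; PAD slots are never maskable."""

    r_geno: float = 0.15
    r_pheno: float = 0.50

    def __post_init__(self) -> None:
        for r in (self.r_geno, self.r_pheno):
            if not 0.0 <= r <= 1.0:
                raise ParameterError("mask rates must lie in [0, 1]")


@dataclass
class SoftLabelSpec:
    """Smoothing mass removed from the true token and spread over the rest."""

    r_smooth: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_smooth < 1.0:
            raise ParameterError("r_smooth must lie in [0, 1)")


@dataclass
class CorruptedCells:
    """Corrupted token batch: MASKed tokens, the masked-position set, labels."""

    tokens: np.ndarray        # (n, S) with MASK at masked positions
    masked: np.ndarray        # (n, S) bool
    labels: np.ndarray        # (n, S) original tokens (valid on masked set)
    pad_mask: np.ndarray      # (n, S) bool


def corrupt(
    cells: TokenizedCells, policy: MaskingPolicy, rng: np.random.Generator
) -> CorruptedCells:
    """Independently mask each non-PAD slot at its modality's rate."""
    n, S = cells.tokens.shape
    F = cells.F
    rates = np.full(S, policy.r_geno)
    rates[:F] = policy.r_pheno
    u = rng.random((n, S))
    masked = (u < rates[None, :]) & ~cells.pad_mask
    tokens = np.where(masked, MASK_ID, cells.tokens)
    return CorruptedCells(
        tokens=tokens, masked=masked, labels=cells.tokens.copy(),
        pad_mask=cells.pad_mask,
    )


def soft_label(
    true_token: int, legal_set: np.ndarray, spec: SoftLabelSpec
) -> np.ndarray:
    """Soft-label distribution over a slot's legal tokens.

    The true token gets 1 - r_smooth; every other legal token gets
    r_smooth/(n-1).  A singleton legal set degenerates to probability 1.
    """
    legal_set = np.asarray(legal_set)
    if true_token not in legal_set:
        raise ParameterError(f"true token {true_token} not in legal set")
    n = len(legal_set)
    if n == 1:
        return np.array([1.0])
    q = np.full(n, spec.r_smooth / (n - 1))
    q[legal_set == true_token] = 1.0 - spec.r_smooth
    return q


def soft_label_entropy(n_legal: int, spec: SoftLabelSpec) -> float:
    """Entropy of the soft-label distribution — the masked-CE lower bound."""
    r = spec.r_smooth
    if n_legal == 1 or r == 0.0:
        return 0.0
    other = r / (n_legal - 1)
    return float(-(1 - r) * np.log(1 - r) - (n_legal - 1) * other * np.log(other))
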