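"""Masked multi-task pretraining, held-out evaluation, and annotation.

Training minimizes the soft-label masked cross-entropy jointly over gene-bin
and phenotype tokens with Adam, a linear warmup / linear decay learning-rate
schedule and global-norm gradient clipping.  Evaluation corrupts a held-out
set once, predicts the masked tokens by argmax over each slot's legal set,
and reports macro precision/recall/F1 per phenotype field, over gene bins,
and a micro-averaged "all" aggregate, plus confusion matrices.  Phenotype
annotation is mask-filling: replace one field's slot with MASK and read the
model's posterior over that field's categories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .corpus import (
    GENE_CLASS,
    MASK_ID,
    CorruptedCells,
    MaskingPolicy,
    SoftLabelSpec,
    TokenizedCells,
    corrupt,
)
from .errors import ParameterError, SchemaError, ValidationError
from .model import (
    ModelConfig,
    ParameterSet,
    build_legal_bias,
    forward,
    forward_logits,
    loss_and_grads,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the original pretraining recipe: Adam, mini-batch 10,
    peak learning rate 2e-5, warmup over the first 10% of steps, 13 epochs.
    Desk-scale runs on synthetic data typically override the learning rate
    upward (e.g. 1e-3) and the epoch count downward.  ``fresh_corruption``
    re-samples the mask pattern every epoch (the pretraining behaviour);
    switching it off trains against one fixed corruption, which is the right
    diagnostic for overfitting a tiny batch to the entropy lower bound.
    """

    batch_size: int = 10
    learning_rate: float = 2e-5
    warmup_ratio: float = 0.1
    epochs: int = 13
    seed: int = 0
    policy: MaskingPolicy = dc_field(default_factory=MaskingPolicy)
    label_spec: SoftLabelSpec = dc_field(default_factory=SoftLabelSpec)
    grad_clip: float = 1.0
    fresh_corruption: bool = True
    single_precision: bool = True

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.epochs <= 0 or self.learning_rate <= 0:
            raise ParameterError("batch size, epochs and learning rate must be positive")
        if not 0.0 <= self.warmup_ratio <= 1.0:
            raise ParameterError("warmup_ratio must lie in [0, 1]")


def lr_at(step: int, total_steps: int, peak: float, warmup_ratio: float) -> float:
    """Linear warmup to ``peak`` at step ceil(warmup_ratio*total), then
    linear decay to 0 at ``total_steps``;  lr(0) = 0."""
    warmup = int(np.ceil(warmup_ratio * total_steps))
    if step <= warmup:
        return peak * step / max(warmup, 1)
    return peak * (total_steps - step) / max(total_steps - warmup, 1)


class AdamState:
    """Standard Adam with bias correction and global-norm gradient clipping."""

    def __init__(self, params: ParameterSet, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: ParameterSet, grads: ParameterSet, lr: float,
             clip: float | None = None) -> None:
        if clip is not None and clip > 0:
            norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if norm > clip:
                grads = {k: g * (clip / norm) for k, g in grads.items()}
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def pretrain(
    cells: TokenizedCells,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    params: ParameterSet | None = None,
    max_steps: int | None = None,
) -> tuple[ParameterSet, list[float]]:
    """Masked multi-task pretraining; returns final weights and the
    per-epoch mean loss history.  Fully reproducible given the seed."""
    if cells.n_cells < train_cfg.batch_size:
        raise ParameterError("corpus smaller than one batch")
    from .model import init_params

    rng = np.random.default_rng(train_cfg.seed)
    dtype = np.float32 if train_cfg.single_precision else np.float64
    if params is None:
        params = init_params(model_cfg, rng, dtype=dtype)
    else:
        params = {k: v.astype(dtype) for k, v in params.items()}
    slot_classes = cells.slot_classes()
    n = cells.n_cells
    steps_per_epoch = n // train_cfg.batch_size
    total_steps = train_cfg.epochs * steps_per_epoch
    if max_steps is not None:
        total_steps = min(total_steps, max_steps)
    adam = AdamState(params)
    history: list[float] = []
    fixed_corr = None
    if not train_cfg.fresh_corruption:
        fixed_corr = corrupt(cells, train_cfg.policy, np.random.default_rng(train_cfg.seed + 1))

    step = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for b in range(steps_per_epoch):
            idx = order[b * train_cfg.batch_size : (b + 1) * train_cfg.batch_size]
            if fixed_corr is None:
                corr = corrupt(cells.subset(idx), train_cfg.policy, rng)
            else:
                corr = CorruptedCells(
                    tokens=fixed_corr.tokens[idx],
                    masked=fixed_corr.masked[idx],
                    labels=fixed_corr.labels[idx],
                    pad_mask=fixed_corr.pad_mask[idx],
                )
            loss, grads = loss_and_grads(
                params, model_cfg, corr, cells.vocab, slot_classes,
                train_cfg.label_spec, train=True, drop_rng=rng,
            )
            if not np.isfinite(loss):
                raise ValidationError(
                    f"training diverged (loss={loss}) at epoch {epoch} step {b}"
                )
            step += 1
            lr = lr_at(step, total_steps, train_cfg.learning_rate, train_cfg.warmup_ratio)
            adam.step(params, grads, lr, train_cfg.grad_clip)
            epoch_losses.append(loss)
            if step >= total_steps:
                break
        history.append(float(np.mean(epoch_losses)))
        logger.info("epoch %d mean loss %.4f", epoch, history[-1])
        if step >= total_steps:
            break
    return params, history


# -- evaluation --------------------------------------------------------------


@dataclass
class EvalReport:
    """Macro P/R/F1 per phenotype field and for gene bins, micro 'all' row,
    and confusion matrices.  Fields with no masked instances carry None."""

    per_field: dict[str, dict]
    genotype: dict
    all_micro: dict

    def rows(self) -> list[dict]:
        out = []
        for name, d in {**self.per_field, "genotype": self.genotype}.items():
            if d is None:
                out.append({"slot": name, "precision": None, "recall": None, "f1": None})
            else:
                out.append({"slot": name, **{k: d[k] for k in ("precision", "recall", "f1")}})
        out.append({"slot": "all", **{k: self.all_micro[k] for k in ("precision", "recall", "f1")}})
        return out

    def to_json(self) -> str:
        def scalar(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            if isinstance(v, list):
                return [scalar(x) for x in v]
            return v

        def clean(d):
            if d is None:
                return None
            return {k: scalar(v) for k, v in d.items()}

        return json.dumps(
            {
                "per_field": {f: clean(d) for f, d in self.per_field.items()},
                "genotype": clean(self.genotype),
                "all": clean(self.all_micro),
            }
        )

    def save(self, directory: str | Path) -> None:
        """Write the report as JSON plus one TSV confusion matrix per slot."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(self.to_json())
        for name, d in {**self.per_field, "genotype": self.genotype}.items():
            if d is None:
                continue
            pd.DataFrame(
                d["confusion"], index=d["classes"], columns=d["classes"]
            ).to_csv(directory / f"confusion_{name}.tsv", sep="\t")


def _macro_metrics(y_true, y_pred, labels) -> dict:
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return {
        "precision": float(p),
        "recall": float(r),
        "f1": float(f1),
        "confusion": cm,
        "classes": list(labels),
        "support": int(len(y_true)),
    }


def evaluate_masked(
    params: ParameterSet,
    model_cfg: ModelConfig,
    cells: TokenizedCells,
    policy: MaskingPolicy,
    seed: int,
) -> EvalReport:
    """Corrupt held-out cells once, predict masked slots, score P/R/F1."""
    corr = corrupt(cells, policy, np.random.default_rng(seed))
    slot_classes = cells.slot_classes()
    logits = forward_logits(params, model_cfg, corr, cells.vocab, slot_classes)
    pred = logits.argmax(-1)

    F = cells.F
    legal = cells.vocab.legal_sets
    per_field: dict[str, dict] = {}
    all_true, all_pred = [], []
    for j, f in enumerate(cells.vocab.fields):
        rows = corr.masked[:, j]
        if rows.sum() == 0:
            per_field[f] = None
            logger.warning("field %r has no masked instances; metrics undefined", f)
            continue
        t, p = corr.labels[rows, j], pred[rows, j]
        per_field[f] = _macro_metrics(t, p, list(legal[f]))
        all_true.append(t)
        all_pred.append(p)

    gene_rows = corr.masked[:, F:]
    if gene_rows.sum() == 0:
        genotype = None
    else:
        t = corr.labels[:, F:][gene_rows]
        p = pred[:, F:][gene_rows]
        genotype = _macro_metrics(t, p, list(legal[GENE_CLASS]))
        all_true.append(t)
        all_pred.append(p)

    yt = np.concatenate(all_true) if all_true else np.array([])
    yp = np.concatenate(all_pred) if all_pred else np.array([])
    mp, mr, mf, _ = precision_recall_fscore_support(
        yt, yp, average="micro", zero_division=0
    )
    all_micro = {
        "precision": float(mp),
        "recall": float(mr),
        "f1": float(mf),
        "support": int(len(yt)),
    }
    return EvalReport(per_field=per_field, genotype=genotype, all_micro=all_micro)


# -- annotation --------------------------------------------------------------


def annotate_phenotype(
    params: ParameterSet,
    model_cfg: ModelConfig,
    cells: TokenizedCells,
    field: str,
) -> tuple[list[str], np.ndarray]:
    """Predict a phenotype field for each cell by mask-filling its slot.

    Returns (predicted category per cell, probability matrix over the
    field's categories).  Deterministic: inference mode, no dropout.
    """
    vocab = cells.vocab
    if field not in vocab.schema:
        raise SchemaError(f"unknown phenotype field {field!r}")
    j = vocab.fields.index(field)
    tokens = cells.tokens.copy()
    tokens[:, j] = MASK_ID
    bias = build_legal_bias(vocab, cells.slot_classes())
    logits, _, _ = forward(params, model_cfg, tokens, cells.pad_mask, bias)
    ids = vocab.legal_sets[field]
    z = logits[:, j, ids]
    z = z - z.max(-1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(-1, keepdims=True)
    cats = vocab.schema[field]
    predicted = [cats[i] for i in probs.argmax(-1)]
    return predicted, probs


def train_validation_split(
    cells: TokenizedCells, val_fraction: float = 0.1, by: str | None = "cell_type",
    seed: int = 0,
) -> tuple[TokenizedCells, TokenizedCells]:
    """Stratified (by a metadata column when available) 90/10 split."""
    rng = np.random.default_rng(seed)
    n = cells.n_cells
    strata = (
        cells.metadata[by].to_numpy()
        if by is not None and by in cells.metadata.columns
        else np.zeros(n)
    )
    val_idx = []
    for s in np.unique(strata):
        idx = np.where(strata == s)[0]
        idx = rng.permutation(idx)
        k = max(1, int(round(val_fraction * len(idx))))
        val_idx.extend(idx[:k])
    val_idx = np.sort(np.array(val_idx))
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    return cells.subset(train_idx), cells.subset(val_idx)
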