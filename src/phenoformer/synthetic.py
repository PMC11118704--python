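"""Synthetic single-cell atlas with planted, recoverable structure.

The generator emulates the shape of a multi-donor human atlas at desk
scale: categorical phenotype fields (sex, age group, tissue, cell type),
sparse negative-binomial counts with log-normal library sizes, and
phenotype-dependent gene programs.  Each tissue and each cell type owns a
"program" of genes whose expression is boosted (log-fold effect with shared
per-cell activity noise, which induces within-module co-expression) in
cells carrying that phenotype value — these genes are the planted markers
and should dominate any dispersion-based HVG ranking.  One designated
polyfunctional gene co-varies with partner module A in cells where a switch
field takes its first half of values and with partner module B otherwise,
planting exactly two context modes.  An "aged" variant mixes program
activities for old cells, creating cross-module correlations of tunable
strength.

What this generator does NOT emulate: batch/donor effects, doublets,
ambient RNA, gene-length or capture biases.  Recovery of the planted truth
therefore demonstrates correctness of the pipeline, not performance on real
tissue atlases.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .atlas import ExpressionMatrix, Schema
from .errors import ParameterError

DEFAULT_SCHEMA: Schema = {
    "sex": ["female", "male"],
    "age": ["young", "middle", "old"],
    "tissue": ["tissueA", "tissueB", "tissueC"],
    "cell_type": ["ct1", "ct2", "ct3", "ct4"],
}


@dataclass
class SyntheticConfig:
    """Atlas-generation parameters; the seed is mandatory.

    ``log_fold`` is the natural-log expression boost of a program gene in
    cells where its program is active (1.5 ~ a 4.5x mean increase);
    ``act_sd`` is the log-sd of the shared per-cell program-activity noise
    that makes module genes co-vary; ``nb_dispersion`` is the negative
    binomial size parameter (smaller = more overdispersed).
    """

    seed: int
    n_cells: int = 2000
    n_genes: int = 300
    schema: Schema = dc_field(default_factory=lambda: dict(DEFAULT_SCHEMA))
    program_fields: tuple[str, ...] = ("tissue", "cell_type")
    program_size: int = 20
    log_fold: float = 1.5
    act_sd: float = 0.25
    nb_dispersion: float = 2.0
    lib_sigma: float = 0.3
    base_mean_range: tuple[float, float] = (0.05, 1.0)
    poly_switch_field: str = "sex"

    def __post_init__(self) -> None:
        n_programs = sum(len(self.schema[f]) for f in self.program_fields) + 2
        if n_programs * self.program_size + 1 > self.n_genes:
            raise ParameterError(
                f"{n_programs} programs x {self.program_size} genes + 1 exceed "
                f"n_genes={self.n_genes}"
            )
        if self.poly_switch_field not in self.schema:
            raise ParameterError(
                f"switch field {self.poly_switch_field!r} not in schema"
            )


@dataclass
class PlantedTruth:
    """Ground truth of the generated atlas, for recovery tests."""

    gene_programs: dict[str, str]             # gene id -> program name
    program_genes: dict[str, list[str]]       # program name -> gene ids
    context_programs: dict[tuple[str, str], str]  # (field, value) -> program
    markers: dict[str, dict[str, list[str]]]  # field -> value -> marker genes
    poly_gene: str
    poly_partners: tuple[str, str]            # partner module names (A, B)
    poly_switch_field: str
    poly_first_half: list[str]                # switch values mapping to mode A
    poly_mode_per_cell: np.ndarray            # "A"/"B" per cell
    config: SyntheticConfig


def _layout(config: SyntheticConfig):
    """Deterministic gene/program layout: program name -> gene index array."""
    gene_ids = [f"G{j:04d}" for j in range(config.n_genes)]
    programs: dict[str, np.ndarray] = {}
    program_context: dict[str, tuple[str, str]] = {}
    cursor = 0
    for f in config.program_fields:
        for v in config.schema[f]:
            name = f"prog_{f}_{v}"
            programs[name] = np.arange(cursor, cursor + config.program_size)
            program_context[name] = (f, v)
            cursor += config.program_size
    for name in ("prog_polyA", "prog_polyB"):
        programs[name] = np.arange(cursor, cursor + config.program_size)
        cursor += config.program_size
    poly_idx = cursor
    return gene_ids, programs, program_context, poly_idx


def _simulate(config: SyntheticConfig, edge_noise: float = 0.0):
    """Draw the atlas.  ``edge_noise`` > 0 mixes program activities for cells
    in the last category of the 'age' field (the aged variant)."""
    rng = np.random.default_rng(config.seed)
    n, G = config.n_cells, config.n_genes
    gene_ids, programs, program_context, poly_idx = _layout(config)
    prog_names = list(programs)

    # phenotypes
    pheno = pd.DataFrame(
        {f: rng.choice(cats, size=n) for f, cats in config.schema.items()}
    )

    # base mean expression, log-uniform across the configured range
    lo, hi = config.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))

    # program activity: indicator x shared lognormal noise per (cell, program)
    switch_cats = config.schema[config.poly_switch_field]
    first_half = switch_cats[: (len(switch_cats) + 1) // 2]
    active = np.zeros((n, len(prog_names)))
    for p, name in enumerate(prog_names):
        if name == "prog_polyA":
            active[:, p] = pheno[config.poly_switch_field].isin(first_half)
        elif name == "prog_polyB":
            active[:, p] = ~pheno[config.poly_switch_field].isin(first_half)
        else:
            f, v = program_context[name]
            active[:, p] = pheno[f] == v
    noise = np.exp(rng.normal(0.0, config.act_sd, size=(n, len(prog_names))))
    activity = active * noise  # (n_cells, n_programs)

    if edge_noise > 0.0:
        # in 'old' cells the tissue program's activity leaks into every
        # program the cell does not express, so genes of different modules
        # share that activity noise and become correlated — specialized
        # (low-connectivity) genes gain links in any similarity network
        old = (pheno["age"] == config.schema["age"][-1]).to_numpy()
        t_idx = [
            i for i, p in enumerate(prog_names) if p.startswith("prog_tissue_")
        ]
        tissue_act = activity[:, t_idx].sum(1, keepdims=True)  # one active/cell
        mixed = activity.copy()
        mixed[old] = activity[old] + edge_noise * (active[old] == 0) * tissue_act[old]
        activity = mixed

    # per-gene log-mean contribution
    log_mu = np.tile(np.log(base), (n, 1))
    for p, name in enumerate(prog_names):
        log_mu[:, programs[name]] += config.log_fold * activity[:, [p]]
    pA, pB = prog_names.index("prog_polyA"), prog_names.index("prog_polyB")
    log_mu[:, poly_idx] += config.log_fold * (activity[:, pA] + activity[:, pB])

    # library size and negative-binomial (gamma-poisson) counts
    lib = np.exp(rng.normal(0.0, config.lib_sigma, size=(n, 1)))
    mu = np.exp(log_mu) * lib
    theta = config.nb_dispersion
    counts = rng.poisson(rng.gamma(theta, mu / theta)).astype(float)

    matrix = ExpressionMatrix(
        values=counts,
        gene_ids=gene_ids,
        cell_ids=[f"cell_{i:05d}" for i in range(n)],
        phenotypes=pheno,
        schema=config.schema,
    )

    program_genes = {p: [gene_ids[j] for j in idx] for p, idx in programs.items()}
    gene_programs = {g: p for p, gs in program_genes.items() for g in gs}
    poly_gene = gene_ids[poly_idx]
    gene_programs[poly_gene] = "poly"
    context_programs = {
        (f, v): f"prog_{f}_{v}"
        for f in config.program_fields
        for v in config.schema[f]
    }
    markers = {
        f: {v: program_genes[f"prog_{f}_{v}"] for v in config.schema[f]}
        for f in config.program_fields
    }
    truth = PlantedTruth(
        gene_programs=gene_programs,
        program_genes=program_genes,
        context_programs=context_programs,
        markers=markers,
        poly_gene=poly_gene,
        poly_partners=("prog_polyA", "prog_polyB"),
        poly_switch_field=config.poly_switch_field,
        poly_first_half=list(first_half),
        poly_mode_per_cell=np.where(
            pheno[config.poly_switch_field].isin(first_half), "A", "B"
        ),
        config=config,
    )
    return matrix, truth


def generate_atlas(config: SyntheticConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate a synthetic atlas with planted programs; bit-reproducible."""
    return _simulate(config, edge_noise=0.0)


def generate_aged_variant(
    atlas: ExpressionMatrix, truth: PlantedTruth, edge_noise: float
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Re-draw the atlas with cross-module activity mixing for 'old' cells.

    ``edge_noise`` in [0, 1] interpolates each old cell's per-program
    activity toward its cross-program mean, correlating genes across
    modules (and thereby raising low-degree gene connectivity in any
    similarity network built downstream).  edge_noise=0 reproduces the
    input atlas exactly.
    """
    if not 0.0 <= edge_noise <= 1.0:
        raise ParameterError("edge_noise must lie in [0, 1]")
    return _simulate(truth.config, edge_noise=edge_noise)


# -- planted embedding clouds (operation-level truth) ------------------------


def generate_mode_embeddings(
    n_cells: int,
    n_modes: int,
    hidden: int,
    separation: float,
    seed: int,
    cell_type: str = "ct1",
    gene: str = "GPOLY",
    n_background_genes: int = 5,
):
    """An EmbeddingTable with one gene whose per-cell vectors form ``n_modes``
    well-separated Gaussian clouds — planted truth for the polyfunctionality
    operation without training a model.  Background genes get unimodal
    clouds.  Returns (table, mode_labels)."""
    from .analysis import EmbeddingTable

    rng = np.random.default_rng(seed)
    modes = rng.integers(0, n_modes, size=n_cells)
    centers = rng.normal(0.0, 1.0, size=(n_modes, hidden))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    vecs = [separation * centers[modes] + rng.normal(0, 1.0, (n_cells, hidden))]
    roles = [np.full(n_cells, gene)]
    cell_idx = [np.arange(n_cells)]
    for b in range(n_background_genes):
        c = rng.normal(0.0, 1.0, size=hidden)
        vecs.append(c + rng.normal(0, 1.0, (n_cells, hidden)))
        roles.append(np.full(n_cells, f"GBG{b:02d}"))
        cell_idx.append(np.arange(n_cells))
    metadata = pd.DataFrame({"cell_type": [cell_type] * n_cells})
    vectors = np.concatenate(vecs)
    table = EmbeddingTable(
        vectors=vectors,
        cell_index=np.concatenate(cell_idx),
        role=np.concatenate(roles),
        metadata=metadata,
        cell_vectors=np.zeros((n_cells, hidden)),
        cell_ids=[f"cell_{i}" for i in range(n_cells)],
        fields=["cell_type"],
    )
    return table, modes
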