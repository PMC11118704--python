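"""Expression-matrix container and single-cell I/O.

The central container couples a cells x genes count/value matrix with a
per-cell table of categorical phenotype fields (e.g. sex, age group, tissue,
cell type) and the declared category sets for each field.  Matrices may be
dense numpy arrays or scipy sparse; all operations accept either.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import SchemaError, ValidationError

Schema = dict[str, list[str]]


def _to_dense(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.todense(), dtype=float)
    return np.asarray(values, dtype=float)


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values plus per-cell phenotype metadata.

    Parameters
    ----------
    values
        Non-negative cells x genes matrix (dense or scipy sparse).
    gene_ids
        Unique gene symbols, one per column.
    cell_ids
        Cell barcodes, one per row.
    phenotypes
        One row per cell; one column per phenotype field, categorical labels.
    schema
        Field name -> ordered list of legal categories.  Derived from the
        observed labels when omitted.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    phenotypes: pd.DataFrame
    schema: Schema = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if not self.schema:
            self.schema = {
                f: sorted(map(str, self.phenotypes[f].unique()))
                for f in self.phenotypes.columns
            }
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.shape
        if n_cells == 0 or n_genes == 0:
            raise ValidationError("expression matrix must have >=1 cell and >=1 gene")
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene_ids are not unique")
        if len(self.cell_ids) != n_cells:
            raise ValidationError(f"{len(self.cell_ids)} cell ids for {n_cells} rows")
        if len(self.phenotypes) != n_cells:
            raise ValidationError("phenotype table must have one row per cell")
        data = self.values.data if sp.issparse(self.values) else np.asarray(self.values)
        if np.isnan(data).any():
            idx = np.argwhere(np.isnan(_to_dense(self.values)))[:5]
            raise ValidationError(f"NaN entries at (cell, gene) indices {idx.tolist()}")
        if (data < 0).sum() > 0:
            idx = np.argwhere(_to_dense(self.values) < 0)[:5]
            raise ValidationError(
                f"negative entries at (cell, gene) indices {idx.tolist()}"
            )
        for f, cats in self.schema.items():
            if f not in self.phenotypes.columns:
                raise SchemaError(f"phenotype field {f!r} missing from metadata")
            bad = set(map(str, self.phenotypes[f].unique())) - set(cats)
            if bad:
                raise SchemaError(f"field {f!r} has undeclared categories {sorted(bad)}")

    # -- conveniences -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.shape[0]

    @property
    def n_genes(self) -> int:
        return self.shape[1]

    def dense(self) -> np.ndarray:
        return _to_dense(self.values)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise SchemaError(f"unknown gene {gene!r}") from None

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        vals = self.values[idx] if sp.issparse(self.values) else self.values[idx, :]
        return ExpressionMatrix(
            values=vals,
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in idx],
            phenotypes=self.phenotypes.iloc[idx].reset_index(drop=True),
            schema=self.schema,
        )

    # -- AnnData bridge -----------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        obs = self.phenotypes.copy()
        obs.index = pd.Index(self.cell_ids, name="cell_id")
        X = self.values if sp.issparse(self.values) else np.asarray(self.values)
        adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs)
        adata.var_names = pd.Index(self.gene_ids, name="gene_id")
        adata.uns["phenotype_schema"] = json.dumps(self.schema)
        return adata

    @classmethod
    def from_anndata(cls, adata, phenotype_fields: list[str] | None = None):
        fields = phenotype_fields or [
            c for c in adata.obs.columns if not c.startswith("_")
        ]
        pheno = adata.obs[fields].astype(str).reset_index(drop=True)
        schema = {}
        if "phenotype_schema" in adata.uns:
            schema = json.loads(adata.uns["phenotype_schema"])
            schema = {f: schema[f] for f in fields if f in schema}
        return cls(
            values=adata.X,
            gene_ids=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            phenotypes=pheno,
            schema=schema,
        )


# -- file formats ------------------------------------------------------------

def read_h5ad(path: str | Path, phenotype_fields: list[str] | None = None) -> ExpressionMatrix:
    import anndata as ad

    return ExpressionMatrix.from_anndata(ad.read_h5ad(path), phenotype_fields)


def write_h5ad(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_anndata().write_h5ad(path)


def read_mtx_bundle(directory: str | Path) -> ExpressionMatrix:
    """Read a Matrix Market bundle: matrix.mtx (genes in columns), genes.tsv,
    barcodes.tsv, metadata.tsv (tab-separated, header row, one row per cell)."""
    from scipy.io import mmread

    directory = Path(directory)
    values = sp.csr_matrix(mmread(directory / "matrix.mtx"))
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t").astype(str)
    return ExpressionMatrix(values, genes, barcodes, meta)


def write_mtx_bundle(matrix: ExpressionMatrix, directory: str | Path) -> None:
    from scipy.io import mmwrite

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(matrix.values))
    pd.Series(matrix.gene_ids).to_csv(
        directory / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False)
    matrix.phenotypes.to_csv(directory / "metadata.tsv", sep="\t", index=False)
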