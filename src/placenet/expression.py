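"""Expression containers and file I/O.

The central container is a genes x cells (or genes x samples) matrix with a
per-cell group label (tumor "T" / normal "N") and a flag recording whether
values are raw counts or log-normalized. Supported on-disk forms: MatrixMarket
sparse triplet (.mtx) with companion gene/cell label TSVs, or a dense TSV with
gene rows and cell columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["ExpressionMatrix", "read_mtx", "read_dense_tsv", "read_groups"]


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values plus cell-group assignments.

    ``values`` is a pandas DataFrame indexed by gene with one column per cell;
    ``cell_groups`` maps cell -> group label and is aligned to the columns.
    ``normalized`` is False for raw counts, True after log-normalization.
    """

    values: pd.DataFrame
    cell_groups: pd.Series | None = None
    normalized: bool = False

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene labels: {dups[:5]}")
        if self.cell_groups is not None:
            self.cell_groups = self.cell_groups.reindex(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cells(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_vector(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)

    def cells_in_group(self, group: str) -> list[str]:
        if self.cell_groups is None:
            raise ValueError("no cell-group assignments attached")
        return list(self.cell_groups.index[self.cell_groups == group])

    def subset_cells(self, cells) -> "ExpressionMatrix":
        groups = self.cell_groups.loc[cells] if self.cell_groups is not None else None
        return replace(self, values=self.values[list(cells)], cell_groups=groups)

    def to_dense_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def read_mtx(mtx_path, genes_path, cells_path, groups: pd.Series | None = None) -> ExpressionMatrix:
    """Read a MatrixMarket genes x cells matrix with label TSVs (one label
    per line; extra columns ignored)."""
    m = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(m):
        m = m.toarray()
    genes = _read_labels(genes_path)
    cells = _read_labels(cells_path)
    if m.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {m.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    df = pd.DataFrame(np.asarray(m, dtype=float), index=genes, columns=cells)
    return ExpressionMatrix(df, cell_groups=groups)


def _read_labels(path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip():
                out.append(line.split("\t")[0])
    return out


def read_dense_tsv(path, groups: pd.Series | None = None, normalized: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float), cell_groups=groups, normalized=normalized)


def read_groups(path) -> pd.Series:
    """Two-column TSV (cell, group) -> Series mapping cell to group label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "group"], dtype=str,
                     comment="#")
    if (df["cell"] == "cell").any():  # tolerate a header row
        df = df[df["cell"] != "cell"]
    return pd.Series(df["group"].values, index=df["cell"].values, name="group")
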