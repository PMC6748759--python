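"""Expression-matrix and annotation I/O plus preprocessing.

The framework consumes a genes-by-cells matrix of non-negative
quantifications (CPM, FPKM or UMI counts).  Two on-disk layouts are
supported: dense TSV/CSV (header row of cell identifiers, first column of
gene identifiers) and Matrix Market triplets with one-column sidecar files
for gene and cell identifiers.  Preprocessing follows the identification
pipeline: log2(x + 1) transform and removal of genes with more than 80%
zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Raised when an input violates a structural constraint."""


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix with identifier bookkeeping.

    Parameters
    ----------
    gene_ids, cell_ids
        Unique identifiers for rows and columns respectively.
    values
        Dense float array of shape ``(n_genes, n_cells)``; all entries
        must be non-negative.
    log_transformed
        Whether entries are already on the log2(x + 1) scale.
    units
        Free-text record of the quantification units ("CPM", "FPKM",
        "UMI", ...); metadata only.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    log_transformed: bool = False
    units: str = "CPM"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Series(ids)
                dup = dup[dup.duplicated()].iloc[0]
                raise ValidationError(f"duplicate {name} identifier: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite entries")
        if (self.values < 0).any():
            g, c = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value for gene {self.gene_ids[g]!r}, "
                f"cell {self.cell_ids[c]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, log_transformed: bool = False, units: str = "CPM"
    ) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(df.index.astype(str)),
            cell_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            log_transformed=log_transformed,
            units=units,
        )

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            cell_ids=[self.cell_ids[i] for i in idx],
            values=self.values[:, idx],
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in genes if g in pos]
        if not idx:
            raise ValidationError("none of the requested genes are in the matrix")
        return replace(
            self,
            gene_ids=[self.gene_ids[i] for i in idx],
            values=self.values[idx, :],
        )


@dataclass
class CellAnnotation:
    """Per-cell class labels (cell type or developmental stage)."""

    cell_ids: list[str]
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.class_labels = [str(l) for l in self.class_labels]
        if len(self.cell_ids) != len(self.class_labels):
            raise ValidationError("cell_ids and class_labels length mismatch")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell identifier in annotation")

    @property
    def n_classes(self) -> int:
        return len(set(self.class_labels))

    def labels_for(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Labels aligned to ``cell_ids`` order; error on missing cells."""
        lookup = dict(zip(self.cell_ids, self.class_labels))
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise ValidationError(f"cells without annotation: {missing[:5]}")
        return np.array([lookup[c] for c in cell_ids])

    def subset(self, cell_ids: Sequence[str]) -> "CellAnnotation":
        labels = self.labels_for(cell_ids)
        return CellAnnotation(list(cell_ids), list(labels))


def _sidecar_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.cells.txt")


def read_expression(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    units: str = "CPM",
) -> ExpressionMatrix:
    """Read a genes x cells matrix from dense TSV/CSV or Matrix Market.

    ``format`` is inferred from the extension when omitted (``.mtx`` ->
    sparse, anything else -> dense).  The sparse layout expects sidecar
    identifier files ``<stem>.genes.txt`` and ``<stem>.cells.txt`` next to
    the ``.mtx`` file unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "dense"
    if format == "mtx":
        gp, cp = _sidecar_paths(path)
        gp = Path(genes_path) if genes_path is not None else gp
        cp = Path(cells_path) if cells_path is not None else cp
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy error text varies
            raise ValidationError(f"malformed Matrix Market file {path}: {exc}") from exc
        values = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        gene_ids = gp.read_text().split()
        cell_ids = cp.read_text().split()
        return ExpressionMatrix(gene_ids, cell_ids, values, units=units)
    if format != "dense":
        raise ValueError(f"unknown format {format!r}")
    sep = "," if path.suffix == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"malformed expression file {path}: {exc}") from exc
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValidationError(
            f"non-numeric entries in {path} (columns {list(bad[:3])})"
        )
    return ExpressionMatrix.from_frame(df, units=units)


def write_expression(m: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write dense TSV/CSV or Matrix Market (with identifier sidecars)."""
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "dense"
    if format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values))
        gp, cp = _sidecar_paths(path)
        gp.write_text("\n".join(m.gene_ids) + "\n")
        cp.write_text("\n".join(m.cell_ids) + "\n")
        return
    sep = "," if path.suffix == ".csv" else "\t"
    m.to_frame().to_csv(path, sep=sep)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy with every entry x replaced by log2(x + 1)."""
    if m.log_transformed:
        raise ValidationError("matrix is already log-transformed")
    return replace(m, values=np.log2(m.values + 1.0), log_transformed=True)


def filter_genes_by_zeros(
    m: ExpressionMatrix, max_zero_fraction: float = 0.8
) -> ExpressionMatrix:
    """Drop genes whose zero fraction strictly exceeds ``max_zero_fraction``.

    A gene with exactly the threshold fraction of zeros is retained: the
    rule removes genes with *more than* the allowed fraction of zeros.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must be in [0, 1]")
    zero_frac = (m.values == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        raise ValidationError(
            "all genes removed by the zero filter; relax max_zero_fraction"
        )
    return replace(
        m,
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        values=m.values[keep, :],
    )


def read_cell_annotation(path: str | Path) -> CellAnnotation:
    """Two-column TSV (cell_id, class_label), with or without a header."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"annotation file {path} needs two columns")
    first = df.iloc[0]
    if str(first[0]).lower() in {"cell_id", "cell", "id"}:
        df = df.iloc[1:]
    return CellAnnotation(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def write_cell_annotation(ann: CellAnnotation, path: str | Path) -> None:
    pd.DataFrame({"cell_id": ann.cell_ids, "class_label": ann.class_labels}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gene_list(path: str | Path) -> list[str]:
    """One gene identifier per line; duplicates collapsed with a warning."""
    path = Path(path)
    genes = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if not genes:
        raise ValidationError(f"gene list {path} is empty")
    seen: dict[str, None] = {}
    dups = []
    for g in genes:
        if g in seen:
            dups.append(g)
        seen[g] = None
    if dups:
        warnings.warn(f"duplicate gene identifiers collapsed: {sorted(set(dups))[:5]}")
    return list(seen)


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")
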