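"""Readers, writers and validated domain containers for count matrices.

Counts are held dense (cells x genes) at the scales this package targets.
Two on-disk dialects are supported:

* Matrix Market coordinate triplets (``.mtx``) with sibling ``barcodes.tsv``
  (cell ids) and ``features.tsv`` (gene ids) files, the convention used by
  most droplet pipelines;
* dense delimited tables (CSV or TSV, auto-detected) with a header row of
  gene ids and a first column of cell ids.

Label and batch annotations are two-column delimited tables mapping cell id
to a category string.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class FormatError(ValueError):
    """Malformed input file (negative entries, duplicate ids, bad shape)."""


class ValidationError(ValueError):
    """Structurally valid file that violates a model precondition."""


@dataclass
class CountMatrix:
    """A cells x genes nonnegative count matrix with identifiers.

    Input counts are integers; derived matrices (imputed output) may carry
    fractional values, so the dtype is float throughout.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("count matrix must be two-dimensional")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelTable:
    """Cell-type assignments; cells absent from ``assignments`` are unlabeled."""

    assignments: dict[str, str]
    types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.types:
            seen: list[str] = []
            for t in self.assignments.values():
                if t not in seen:
                    seen.append(t)
            self.types = seen

    @property
    def C(self) -> int:
        return len(self.types)

    @property
    def n_labeled(self) -> int:
        return len(self.assignments)

    def indices(self, cells: CountMatrix) -> np.ndarray:
        """Per-cell integer type index aligned to ``cells``; -1 for unlabeled."""
        lut = {t: i for i, t in enumerate(self.types)}
        return np.array(
            [lut[self.assignments[c]] if c in self.assignments else -1 for c in cells.cell_ids],
            dtype=int,
        )


@dataclass
class BatchTable:
    """Batch assignment per cell; must cover every cell when supplied."""

    assignments: dict[str, str]
    batches: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.batches:
            seen: list[str] = []
            for b in self.assignments.values():
                if b not in seen:
                    seen.append(b)
            self.batches = seen
        if not self.batches:
            raise ValidationError("batch table must define at least one batch")

    def indices(self, cells: CountMatrix) -> np.ndarray:
        missing = [c for c in cells.cell_ids if c not in self.assignments]
        if missing:
            raise ValidationError(f"cells without batch assignment: {missing[:5]}")
        lut = {b: i for i, b in enumerate(self.batches)}
        return np.array([lut[self.assignments[c]] for c in cells.cell_ids], dtype=int)


def _validate_counts(values: np.ndarray, cell_ids: list[str], gene_ids: list[str]) -> CountMatrix:
    if len(set(cell_ids)) != len(cell_ids):
        raise FormatError("duplicate cell identifiers")
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError("duplicate gene identifiers")
    if np.any(values < 0):
        raise FormatError("negative entries in count matrix")
    if not np.all(np.isfinite(values)):
        raise FormatError("non-finite entries in count matrix")
    totals = values.sum(axis=1)
    dead = np.where(totals == 0)[0]
    if dead.size:
        names = [cell_ids[i] for i in dead[:5]]
        raise ValidationError(
            f"{dead.size} cell(s) with total count 0 (size factors undefined): {names}"
        )
    return CountMatrix(values, list(cell_ids), list(gene_ids))


def _sibling_paths(mtx_path: str) -> tuple[str, str]:
    d = os.path.dirname(os.path.abspath(mtx_path))
    return os.path.join(d, "barcodes.tsv"), os.path.join(d, "features.tsv")


def _read_id_column(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(path: str, orientation: str = "cells-as-rows") -> CountMatrix:
    """Load a count matrix and validate it into cells x genes orientation.

    ``orientation`` states how the *file* is laid out; the returned matrix is
    always cells x genes.
    """
    if orientation not in ("cells-as-rows", "genes-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if path.endswith(".mtx"):
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        rows_path, cols_path = _sibling_paths(path)
        row_ids = _read_id_column(rows_path)
        col_ids = _read_id_column(cols_path)
        if mat.shape != (len(row_ids), len(col_ids)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match annotation files "
                f"({len(row_ids)} x {len(col_ids)})"
            )
    else:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        mat = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    if orientation == "genes-as-rows":
        mat = mat.T
        row_ids, col_ids = col_ids, row_ids
    return _validate_counts(mat, row_ids, col_ids)


def read_labels(path: str, cells: CountMatrix) -> LabelTable:
    """Read a two-column (cell id, label) table; unknown cell ids are errors."""
    known = set(cells.cell_ids)
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) < 2:
                raise FormatError(f"expected two columns, got: {line!r}")
            cid, lab = parts[0].strip(), parts[1].strip()
            if cid not in known:
                raise ValidationError(f"label references unknown cell id {cid!r}")
            assignments[cid] = lab
    return LabelTable(assignments)


def read_batches(path: str, cells: CountMatrix) -> BatchTable:
    table = read_labels(path, cells)  # same two-column format and checks
    bt = BatchTable(dict(table.assignments))
    bt.indices(cells)  # enforce total coverage
    return bt


def write_labels(labels: LabelTable, path: str) -> None:
    with open(path, "w") as fh:
        for cid, lab in labels.assignments.items():
            fh.write(f"{cid}\t{lab}\n")


def write_matrix(M: CountMatrix, path: str, dialect: str = "dense") -> None:
    """Write a (possibly fractional) matrix; round-trips within 1e-9."""
    if not np.all(np.isfinite(M.values)):
        raise ValueError("refusing to write non-finite entries")
    if dialect == "matrix-market":
        if not path.endswith(".mtx"):
            path = path + ".mtx"
        spio.mmwrite(path, sparse.coo_matrix(M.values), precision=12)
        rows_path, cols_path = _sibling_paths(path)
        with open(rows_path, "w") as fh:
            fh.write("\n".join(M.cell_ids) + "\n")
        with open(cols_path, "w") as fh:
            fh.write("\n".join(M.gene_ids) + "\n")
    elif dialect == "dense":
        df = pd.DataFrame(M.values, index=M.cell_ids, columns=M.gene_ids)
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df.to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_matrix_unvalidated(path: str) -> CountMatrix:
    """Load a real-valued matrix (e.g. an imputed output) without the
    integer-count validation; ids and nonnegativity are still checked."""
    if path.endswith(".mtx"):
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        rows_path, cols_path = _sibling_paths(path)
        return CountMatrix(np.asarray(mat, dtype=float), _read_id_column(rows_path), _read_id_column(cols_path))
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return CountMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns])
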