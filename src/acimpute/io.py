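"""Reading and writing expression matrices and label files.

Two on-disk conventions are supported: dense delimited text (genes in rows,
cells in columns, first column = gene ids, header row = cell ids; tab for
``.tsv``/``.txt``, comma for ``.csv``) and MatrixMarket sparse triplets
(``matrix.mtx`` with 1-based indices plus ``genes.tsv`` and ``barcodes.tsv``
sidecars in the same directory).  Dense values are written at full float
precision so that read/write round-trips are exact — the zero-only merge
downstream relies on observed values surviving I/O bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, LabelVector

__all__ = ["read_matrix", "write_matrix", "read_labels", "write_labels"]

GENES_SIDECAR = "genes.tsv"
BARCODES_SIDECAR = "barcodes.tsv"


def _infer_format(path: Path) -> str:
    return "mtx" if path.suffix == ".mtx" else "dense_delimited"


def _dense_sep(path: Path) -> str:
    return "," if path.suffix == ".csv" else "\t"


def read_matrix(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a gene x cell matrix from dense delimited text or MatrixMarket.

    ``format`` is ``"dense_delimited"`` or ``"mtx"``; when omitted it is
    inferred from the file extension.  Errors (missing sidecars, dimension
    mismatches, negative values, malformed headers) raise ``ValueError``
    with a description of the offending content.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"input file does not exist: {path}")
    fmt = format or _infer_format(path)
    if fmt == "dense_delimited":
        return _read_dense(path)
    if fmt == "mtx":
        return _read_mtx(path)
    raise ValueError(f"unknown matrix format '{fmt}'")


def _read_dense(path: Path) -> CountMatrix:
    try:
        # round_trip parser: values written at repr precision read back bit-exact
        df = pd.read_csv(
            path, sep=_dense_sep(path), index_col=0, float_precision="round_trip"
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise ValueError(f"malformed dense matrix file {path}: {err}") from err
    if df.shape[1] == 0:
        raise ValueError(f"dense matrix file {path} has no cell columns")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as err:
        raise ValueError(f"non-numeric entry in {path}: {err}") from err
    if np.any(values < 0):
        g, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative value in {path} at gene '{df.index[g]}', cell '{df.columns[c]}'"
        )
    return CountMatrix(values, df.index.astype(str), df.columns.astype(str))


def _read_sidecar(path: Path, expected: int, what: str) -> list[str]:
    if not path.exists():
        raise ValueError(f"missing {what} sidecar: {path}")
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    if len(ids) != expected:
        raise ValueError(
            f"{what} sidecar {path} lists {len(ids)} entries but the matrix has {expected}"
        )
    return ids


def _read_mtx(path: Path) -> CountMatrix:
    try:
        mat = scipy.io.mmread(path)
    except ValueError as err:
        raise ValueError(f"malformed MatrixMarket file {path}: {err}") from err
    values = np.asarray(
        mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
    )
    if np.any(values < 0):
        g, c = np.argwhere(values < 0)[0]
        raise ValueError(f"negative value in {path} at triplet row {g + 1}, column {c + 1}")
    genes = _read_sidecar(path.parent / GENES_SIDECAR, values.shape[0], "gene")
    cells = _read_sidecar(path.parent / BARCODES_SIDECAR, values.shape[1], "barcode")
    return CountMatrix(values, genes, cells)


def write_matrix(m: CountMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix so that :func:`read_matrix` recovers it exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = format or _infer_format(path)
    if fmt == "dense_delimited":
        df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids)
        # pandas default float formatting is shortest-round-trip repr
        df.to_csv(path, sep=_dense_sep(path))
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values), precision=17)
        (path.parent / GENES_SIDECAR).write_text("".join(f"{g}\n" for g in m.gene_ids))
        (path.parent / BARCODES_SIDECAR).write_text("".join(f"{c}\n" for c in m.cell_ids))
    else:
        raise ValueError(f"unknown matrix format '{fmt}'")


def read_labels(path: str | Path) -> LabelVector:
    """Read a two-column TSV (cell_id, label) with a header line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} must have two columns (cell_id, label)")
    return LabelVector(df.iloc[:, 1].to_numpy(), df.iloc[:, 0].to_numpy())


def write_labels(labels: LabelVector, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cell_id": labels.cell_ids, "label": labels.labels}).to_csv(
        path, sep="\t", index=False
    )
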