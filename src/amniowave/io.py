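"""Reading and writing count matrices (TSV and Matrix Market) with metadata.

TSV layout: first column ``gene_id``, remaining columns are sample IDs,
values are integer counts.  Sample metadata travels in a sidecar CSV named
``<stem>.samples.csv`` with columns ``sample_id,timepoint_hr,condition,replicate``.

MTX layout: Matrix Market coordinate integer file plus ``genes.csv``
(column ``gene_id``) and ``samples.csv`` (metadata, as above) in the same
directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .counts import SAMPLE_META_COLUMNS, CountMatrix
from .errors import ParseError
from .projection import ReferenceAtlas

_META_DTYPES = {"timepoint_hr": float, "condition": str, "replicate": "Int64"}


def _meta_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".samples.csv")


def _read_sample_meta(path: Path, sample_ids: list[str]) -> pd.DataFrame:
    if not path.exists():
        # metadata is optional on read; synthesize an empty frame
        return pd.DataFrame(
            {"timepoint_hr": np.nan, "condition": "", "replicate": pd.array([pd.NA] * len(sample_ids), dtype="Int64")},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    meta = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    meta = meta.set_index("sample_id")
    for col in SAMPLE_META_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan if col == "timepoint_hr" else ("" if col == "condition" else pd.NA)
    meta = meta[list(SAMPLE_META_COLUMNS)].astype(_META_DTYPES)
    missing = set(sample_ids) - set(meta.index)
    if missing:
        raise ParseError(f"{path}: metadata missing for samples {sorted(missing)[:5]}")
    return meta.loc[sample_ids]


def _write_sample_meta(meta: pd.DataFrame, path: Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_count_matrix(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix (``tsv`` or ``mtx``) and its metadata sidecar(s).

    Raises :class:`ParseError` on duplicate IDs (with the 1-based line
    number), non-integer counts, or coordinates outside the declared MTX
    shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "mtx":
        return _read_mtx(path)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")


def write_count_matrix(matrix: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        out = matrix.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
        _write_sample_meta(matrix.sample_meta, _meta_sidecar(path))
    elif format == "mtx":
        sparse = scipy.sparse.coo_matrix(matrix.counts.to_numpy())
        scipy.io.mmwrite(str(path), sparse, field="integer")
        directory = path.parent
        pd.Series(matrix.gene_ids, name="gene_id").to_csv(directory / "genes.csv", index=False)
        _write_sample_meta(matrix.sample_meta, directory / "samples.csv")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")


def _read_tsv(path: Path) -> CountMatrix:
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
    if not header or header[0] != "gene_id":
        raise ParseError(f"{path}:1: header must start with 'gene_id', got {header[:1]!r}")
    sample_ids = header[1:]
    seen: dict[str, int] = {}
    for j, sid in enumerate(sample_ids):
        if sid in seen:
            raise ParseError(f"{path}:1: duplicate sample ID {sid!r}")
        seen[sid] = j

    table = pd.read_csv(path, sep="\t", index_col=0, dtype={"gene_id": str})
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        # +2: one for header, one for 1-based numbering of the first occurrence's dup
        line = int(np.where(table.index == dup)[0][1]) + 2
        raise ParseError(f"{path}:{line}: duplicate gene ID {dup!r}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        bad = np.where(~np.isclose(values.astype(float), np.round(values.astype(float))))
        if len(bad[0]):
            line = int(bad[0][0]) + 2
            raise ParseError(f"{path}:{line}: non-integer count {values[bad[0][0], bad[1][0]]!r}")
        table = table.round().astype(np.int64)
    meta = _read_sample_meta(_meta_sidecar(path), sample_ids)
    return CountMatrix(table, meta)


def _read_mtx(path: Path) -> CountMatrix:
    directory = path.parent
    genes_file = directory / "genes.csv"
    samples_file = directory / "samples.csv"
    if not genes_file.exists():
        raise ParseError(f"{genes_file}: companion gene annotation file not found")
    try:
        sparse = scipy.io.mmread(str(path))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    dense = np.asarray(sparse.todense() if scipy.sparse.issparse(sparse) else sparse)
    genes = pd.read_csv(genes_file, dtype=str)["gene_id"].tolist()
    if len(genes) != dense.shape[0]:
        raise ParseError(
            f"{genes_file}: {len(genes)} gene IDs but matrix declares {dense.shape[0]} rows"
        )
    if genes_file.exists() and samples_file.exists():
        meta_raw = pd.read_csv(samples_file, dtype={"sample_id": str})
        sample_ids = meta_raw["sample_id"].tolist()
    else:
        sample_ids = [f"S{j + 1}" for j in range(dense.shape[1])]
    if len(sample_ids) != dense.shape[1]:
        raise ParseError(
            f"{samples_file}: {len(sample_ids)} sample IDs but matrix declares {dense.shape[1]} columns"
        )
    if not np.allclose(dense, np.round(dense)):
        raise ParseError(f"{path}: matrix contains non-integer counts")
    table = pd.DataFrame(
        np.round(dense).astype(np.int64),
        index=pd.Index(genes, name="gene_id"),
        columns=sample_ids,
    )
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise ParseError(f"{genes_file}: duplicate gene ID {dup!r}")
    meta = _read_sample_meta(samples_file, sample_ids)
    return CountMatrix(table, meta)


def write_reference_atlas(atlas: ReferenceAtlas, directory: str | Path) -> None:
    """Write an atlas as ``matrix.mtx`` + ``genes.csv`` + ``cells.csv``.

    ``cells.csv`` carries columns ``cell_id,label,x,y``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(atlas.counts.to_numpy())
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse, field="integer")
    pd.Series(atlas.gene_ids, name="gene_id").to_csv(directory / "genes.csv", index=False)
    cells = pd.DataFrame(
        {
            "cell_id": atlas.cell_ids,
            "label": atlas.labels.to_numpy(),
            "x": atlas.embedding["x"].to_numpy(),
            "y": atlas.embedding["y"].to_numpy(),
        }
    )
    cells.to_csv(directory / "cells.csv", index=False)


def read_reference_atlas(directory: str | Path) -> ReferenceAtlas:
    """Read an atlas written by :func:`write_reference_atlas`."""
    directory = Path(directory)
    matrix_file = directory / "matrix.mtx"
    for required in (matrix_file, directory / "genes.csv", directory / "cells.csv"):
        if not required.exists():
            raise ParseError(f"{required}: atlas component not found")
    try:
        sparse = scipy.io.mmread(str(matrix_file))
    except ValueError as exc:
        raise ParseError(f"{matrix_file}: {exc}") from exc
    dense = np.asarray(sparse.todense() if scipy.sparse.issparse(sparse) else sparse)
    genes = pd.read_csv(directory / "genes.csv", dtype=str)["gene_id"].tolist()
    cells = pd.read_csv(directory / "cells.csv", dtype={"cell_id": str, "label": str})
    if dense.shape != (len(genes), len(cells)):
        raise ParseError(
            f"{matrix_file}: shape {dense.shape} does not match "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    counts = pd.DataFrame(
        dense.astype(np.int64),
        index=pd.Index(genes, name="gene_id"),
        columns=cells["cell_id"].tolist(),
    )
    labels = pd.Series(cells["label"].to_numpy(), index=cells["cell_id"], name="cluster")
    embedding = pd.DataFrame(
        {"x": cells["x"].to_numpy(float), "y": cells["y"].to_numpy(float)},
        index=cells["cell_id"],
    )
    return ReferenceAtlas(counts=counts, labels=labels, embedding=embedding)
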