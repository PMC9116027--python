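"""Readers and writers for count matrices, compositions and labels.

Count matrices are gene-major on disk. Two formats are supported:

* MatrixMarket coordinate (``.mtx``) with companion ID files
  ``<stem>.genes.tsv`` and ``<stem>.locations.tsv`` (one ID per line);
* dense delimited CSV/TSV with a header row of location IDs and a first
  column of gene IDs.

Gzipped variants (``.gz``) are accepted everywhere. Dense inputs whose
header matches the first column's style as genes are transposed with a
warning. Offsets are never read from disk — they are recomputed column sums.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_compositions",
    "write_compositions",
    "read_labels",
    "write_labels",
]

logger = logging.getLogger(__name__)


def _strip_gz(path: Path) -> Path:
    return path.with_suffix("") if path.suffix == ".gz" else path


def _detect_format(path: Path) -> str:
    suffix = _strip_gz(path).suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix in (".csv", ".txt"):
        return "csv"
    if suffix == ".tsv":
        return "tsv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def _id_file_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = _strip_gz(mtx_path)
    base = stem.with_suffix("")
    return (
        base.with_suffix(".genes.tsv"),
        base.with_suffix(".locations.tsv"),
    )


def _read_ids(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    if not path.exists() and path.with_suffix(path.suffix + ".gz").exists():
        path = path.with_suffix(path.suffix + ".gz")
        opener = gzip.open
    with opener(path, "rt") as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def read_counts(path, format: str | None = None) -> CountMatrix:
    """Load a gene x location count matrix from MTX or dense CSV/TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)

    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:
            raise ValueError(f"malformed MatrixMarket file {path.name!r}: {exc}") from exc
        genes_path, locs_path = _id_file_paths(path)
        gene_ids = _read_ids(genes_path)
        loc_ids = _read_ids(locs_path)
        mat = sp.coo_matrix(mat)
        if mat.shape[0] != len(gene_ids):
            raise ValueError(
                f"dimension mismatch: MTX has {mat.shape[0]} rows but "
                f"{genes_path.name} lists {len(gene_ids)} genes"
            )
        if mat.shape[1] != len(loc_ids):
            raise ValueError(
                f"dimension mismatch: MTX has {mat.shape[1]} columns but "
                f"{locs_path.name} lists {len(loc_ids)} locations"
            )
        if (mat.data < 0).any():
            raise ValueError("negative entries in count matrix")
        if not np.allclose(mat.data, np.rint(mat.data), rtol=0, atol=1e-8):
            raise ValueError("non-integer entries in count matrix")
        return CountMatrix(mat, gene_ids, loc_ids)

    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ValueError(f"malformed header or body in {path.name!r}: {exc}") from exc
    if df.empty:
        raise ValueError(f"empty count matrix in {path.name!r}")
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"non-numeric entries in {path.name!r}")
    if (arr < 0).any():
        raise ValueError("negative entries in count matrix")
    gene_ids = [str(i) for i in df.index]
    loc_ids = [str(c) for c in df.columns]
    if _looks_transposed(gene_ids, loc_ids):
        logger.warning("input looks location-major; transposing %s", path.name)
        df = df.T
        gene_ids, loc_ids = loc_ids, gene_ids
        arr = df.to_numpy()
    return CountMatrix(arr, gene_ids, loc_ids)


def _looks_transposed(rows: list[str], cols: list[str]) -> bool:
    # heuristic: header ids named gene*/ENSG* while rows look like locations
    def frac_genes(ids):
        return np.mean([i.lower().startswith(("gene", "ensg", "ensm")) for i in ids])

    return frac_genes(cols) > 0.9 and frac_genes(rows) < 0.1


def write_counts(m: CountMatrix, path, format: str | None = None) -> None:
    """Write a CountMatrix as MTX (+ID files) or dense CSV/TSV."""
    path = Path(path)
    fmt = format or _detect_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        scipy.io.mmwrite(str(_strip_gz(path)), sp.coo_matrix(m.counts))
        genes_path, locs_path = _id_file_paths(path)
        genes_path.write_text("\n".join(m.gene_ids) + "\n")
        locs_path.write_text("\n".join(m.location_ids) + "\n")
        return
    sep = "\t" if fmt == "tsv" else ","
    pd.DataFrame(m.counts, index=m.gene_ids, columns=m.location_ids).to_csv(
        path, sep=sep
    )


def read_compositions(path) -> pd.DataFrame:
    """Location x cell-type composition table (rows sum to 1)."""
    path = Path(path)
    sep = "\t" if _strip_gz(path).suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"empty composition matrix in {path.name!r}")
    return df


def write_compositions(comp: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if _strip_gz(path).suffix.lower() == ".tsv" else ","
    comp.to_csv(path, sep=sep)


def read_labels(path) -> pd.Series:
    """Two-column TSV (location id, cluster label) -> Series."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    if df.shape[1] != 1:
        raise ValueError("label file must have exactly two columns")
    return df.iloc[:, 0]


def write_labels(location_ids, labels, path) -> None:
    pd.DataFrame({"location": location_ids, "cluster": labels}).to_csv(
        path, sep="\t", index=False
    )
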