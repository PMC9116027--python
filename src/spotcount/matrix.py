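"""Gene-by-location count matrix container.

The matrix is gene-major (genes are rows). Per-location offsets are always
recomputed from the matrix itself (column sums), never cached from disk, so
filtering and subsetting keep offsets consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """Non-negative integer counts with gene and location identifiers.

    Parameters
    ----------
    counts
        ``(n_genes, n_locations)`` array of non-negative integers. Sparse
        inputs are accepted and densified (all analyses here are desk-scale).
    gene_ids, location_ids
        Unique string identifiers for rows and columns.
    """

    counts: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    location_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene x location matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            rounded = np.rint(as_float)
            if not np.allclose(as_float, rounded, rtol=0, atol=1e-8):
                raise ValueError("counts must be integral")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        g, n = self.counts.shape
        if not self.gene_ids:
            self.gene_ids = [f"gene{i}" for i in range(g)]
        if not self.location_ids:
            self.location_ids = [f"loc{i}" for i in range(n)]
        self.gene_ids = [str(x) for x in self.gene_ids]
        self.location_ids = [str(x) for x in self.location_ids]
        if len(self.gene_ids) != g:
            raise ValueError(
                f"gene id count {len(self.gene_ids)} does not match {g} rows"
            )
        if len(self.location_ids) != n:
            raise ValueError(
                f"location id count {len(self.location_ids)} does not match {n} columns"
            )
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_locations(self) -> int:
        return self.counts.shape[1]

    @property
    def offsets(self) -> np.ndarray:
        """Per-location totals N_i (column sums), used as model offsets."""
        return self.counts.sum(axis=0).astype(float)

    def gene(self, gene_id: str) -> np.ndarray:
        return self.counts[self.gene_ids.index(gene_id)]

    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.counts[idx],
            [self.gene_ids[i] for i in idx],
            list(self.location_ids),
        )

    def subset_locations(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.counts[:, idx],
            list(self.gene_ids),
            [self.location_ids[i] for i in idx],
        )

    def zero_fraction(self) -> float:
        """Overall fraction of zero entries."""
        return float((self.counts == 0).mean())
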