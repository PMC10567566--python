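"""Annotated gene x nucleus count matrix.

The central container for raw UMI counts plus per-nucleus metadata
(lane, animal, cell type, perturbation/condition label). Counts are
stored sparse in genes-x-nuclei orientation; all indexing is 0-based
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["AnnotatedCountMatrix"]


@dataclass
class AnnotatedCountMatrix:
    """Sparse gene x nucleus UMI count matrix with nucleus metadata.

    Parameters
    ----------
    counts
        Sparse integer matrix, shape ``(n_genes, n_nuclei)``.
    genes
        Unique gene identifiers, length ``n_genes``.
    barcodes
        Unique nucleus barcodes, length ``n_nuclei``; aligned with the
        columns of ``counts`` and the rows of ``metadata``.
    metadata
        Per-nucleus table indexed by barcode. Conventional columns:
        ``lane``, ``animal``, ``cell_type``, ``perturbation``.
    """

    counts: sp.csr_matrix
    genes: pd.Index
    barcodes: pd.Index
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes, name="gene")
        self.barcodes = pd.Index(self.barcodes, name="barcode")
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if not self.genes.is_unique:
            raise ValueError("gene identifiers must be unique")
        if not self.barcodes.is_unique:
            raise ValueError("barcodes must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=self.barcodes)
        else:
            missing = self.barcodes.difference(self.metadata.index)
            if len(missing):
                raise ValueError(
                    f"metadata missing {len(missing)} barcodes "
                    f"(first: {missing[0]!r})"
                )
            self.metadata = self.metadata.loc[self.barcodes]

    # -- basic introspection -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_nuclei(self) -> int:
        return len(self.barcodes)

    def library_sizes(self) -> np.ndarray:
        """Total UMI per nucleus (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    # -- subsetting ----------------------------------------------------------

    def subset_nuclei(self, mask_or_barcodes) -> "AnnotatedCountMatrix":
        """Column subset by boolean mask or barcode list (order preserved)."""
        if isinstance(mask_or_barcodes, (list, tuple, pd.Index)) or (
            isinstance(mask_or_barcodes, np.ndarray)
            and mask_or_barcodes.dtype.kind not in "b"
        ):
            idx = self.barcodes.get_indexer(pd.Index(mask_or_barcodes))
            if (idx < 0).any():
                raise KeyError("unknown barcodes requested")
        else:
            idx = np.flatnonzero(np.asarray(mask_or_barcodes))
        return AnnotatedCountMatrix(
            counts=self.counts[:, idx],
            genes=self.genes,
            barcodes=self.barcodes[idx],
            metadata=self.metadata.iloc[idx],
        )

    def subset_genes(self, genes) -> "AnnotatedCountMatrix":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            raise KeyError("unknown genes requested")
        return AnnotatedCountMatrix(
            counts=self.counts[idx],
            genes=self.genes[idx],
            barcodes=self.barcodes,
            metadata=self.metadata,
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())
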