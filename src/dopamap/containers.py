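"""Core in-memory containers shared by every pipeline stage.

The universal substrate is :class:`CountMatrix`: a sparse gene-by-cell
matrix of non-negative integer UMI (or transcript) counts together with
per-cell and per-gene annotation tables. Cells carry sample / genotype
labels and, for spatial datasets, micrometer coordinates and segmented
cell volume; genes carry mitochondrial / ribosomal flags used by QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "NormalizedMatrix"]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class CountMatrix:
    """Sparse genes x cells count matrix with aligned annotations.

    Parameters
    ----------
    counts
        Non-negative counts, shape ``(n_genes, n_cells)``. Any scipy sparse
        format or dense array is accepted and stored as CSR.
    gene_ids, cell_ids
        Unique string identifiers for the rows / columns.
    cell_meta
        Optional table indexed by cell id (columns such as ``sample``,
        ``genotype``, ``x_um``, ``y_um``, ``volume_um3``, ``truth_leaf``).
    gene_meta
        Optional table indexed by gene id (``is_mito``, ``is_ribo`` flags).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    gene_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.all(np.isfinite(self.counts.data)):
            raise ValueError("counts must be finite")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        ng, nc = self.counts.shape
        if len(self.gene_ids) != ng or len(self.cell_ids) != nc:
            raise ValueError(
                f"shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.cell_ids)} cells"
            )
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        else:
            self.gene_meta = self.gene_meta.reindex(self.gene_ids)

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Positions of ``genes`` in the gene axis; raises on missing symbols."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:10]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def cell_index(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise KeyError(f"cells absent from matrix: {sorted(missing)[:10]}")
        return np.array([lookup[c] for c in cells], dtype=int)

    def subset_cells(self, keep) -> "CountMatrix":
        """New matrix restricted to cells given by id or boolean/integer mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            idx = self.cell_index(keep)
        return CountMatrix(
            self.counts[:, idx],
            self.gene_ids,
            self.cell_ids[idx],
            self.cell_meta.iloc[idx],
            self.gene_meta,
        )

    def subset_genes(self, keep) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            idx = self.gene_index(keep)
        return CountMatrix(
            self.counts[idx],
            self.gene_ids[idx],
            self.cell_ids,
            self.cell_meta,
            self.gene_meta.iloc[idx],
        )


@dataclass
class NormalizedMatrix:
    """Depth-normalized log expression plus the z-scored form used for PCA.

    ``lognorm`` is ``log1p(count / depth * target_sum)`` per cell (genes x
    cells, sparse); ``scaled`` is the per-gene z-scored dense form, clipped
    at ``+-scale_cap``, laid out cells x genes for the decomposition step.
    """

    lognorm: sp.csr_matrix
    scaled: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    target_sum: float
    scale_cap: float
    gene_means: np.ndarray
    gene_stds: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.lognorm.shape[0]

    @property
    def n_cells(self) -> int:
        return self.lognorm.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:10]}")
        return np.array([lookup[g] for g in genes], dtype=int)
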