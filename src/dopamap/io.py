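"""Readers and writers for the standard on-disk formats.

Count matrices travel as MatrixMarket triplets with ``genes.tsv`` /
``barcodes.tsv`` sidecars and a ``cell_meta.csv`` table (the layout that
droplet pipelines emit), or as dense CSV for small instances. Gene sets
use GMT, regions GeoJSON, ground truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import CountMatrix
from .spatial import RegionMap
from .synthio import TruthSpec

__all__ = [
    "write_count_matrix",
    "read_count_matrix",
    "write_truth",
    "read_truth",
    "write_regions",
    "read_regions",
]


def write_count_matrix(matrix: CountMatrix, directory, fmt: str = "mtx") -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + cell_meta.csv (+ gene_meta.csv),
    or a single dense counts.csv for ``fmt="csv"``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        mmwrite(str(d / "matrix.mtx"), matrix.counts.tocoo(), field="integer")
        pd.Series(matrix.gene_ids).to_csv(d / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series(matrix.cell_ids).to_csv(d / "barcodes.tsv", sep="\t", index=False, header=False)
    elif fmt == "csv":
        dense = pd.DataFrame(
            np.asarray(matrix.counts.todense()), index=matrix.gene_ids, columns=matrix.cell_ids
        )
        dense.to_csv(d / "counts.csv")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    matrix.cell_meta.to_csv(d / "cell_meta.csv")
    matrix.gene_meta.to_csv(d / "gene_meta.csv")


def read_count_matrix(directory, fmt: str = "mtx") -> CountMatrix:
    """Inverse of :func:`write_count_matrix`; lossless for integer counts."""
    d = Path(directory)
    if fmt == "mtx":
        counts = sp.csr_matrix(mmread(str(d / "matrix.mtx")))
        genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
        cells = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
        if counts.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {counts.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
    elif fmt == "csv":
        dense = pd.read_csv(d / "counts.csv", index_col=0)
        genes = dense.index.astype(str).to_numpy()
        cells = dense.columns.astype(str).to_numpy()
        counts = sp.csr_matrix(dense.to_numpy())
    else:
        raise ValueError(f"unknown format {fmt!r}")
    cell_meta = gene_meta = None
    if (d / "cell_meta.csv").exists():
        cell_meta = pd.read_csv(d / "cell_meta.csv", index_col=0)
        cell_meta.index = cell_meta.index.astype(str)
    if (d / "gene_meta.csv").exists():
        gene_meta = pd.read_csv(d / "gene_meta.csv", index_col=0)
        gene_meta.index = gene_meta.index.astype(str)
    return CountMatrix(counts, genes, cells, cell_meta, gene_meta)


def write_truth(truth: TruthSpec, path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path) -> TruthSpec:
    return TruthSpec.from_json(Path(path).read_text())


def write_regions(regions: RegionMap, path) -> None:
    Path(path).write_text(json.dumps(regions.to_geojson(), indent=1))


def read_regions(path) -> RegionMap:
    return RegionMap.from_geojson(json.loads(Path(path).read_text()))
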