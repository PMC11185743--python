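"""Per-cell quality control, sex inference, and doublet-cluster flagging.

QC filtering follows the per-sample open-window convention of droplet
single-nucleus pipelines: a cell is kept iff it lies strictly inside every
bound of the window that applies to its sample (e.g. ``n_features > 1200``
drops a cell with exactly 1200 detected genes). Mito/ribo fractions are
stored on the percent scale (0-100), matching the convention in which a
cutoff of 0.5 means half a percent of counts.

Spatial (imaging) datasets are filtered on segmented cell volume — cells
outside [min_volume, max_volume] um^3 reflect poor segmentation — and on a
minimum number of detected transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "QCWindow",
    "compute_qc",
    "filter_cells",
    "filter_spatial_cells",
    "infer_sex",
    "flag_doublet_clusters",
]


@dataclass
class QCWindow:
    """Open-interval bounds per QC metric for one sample (or "all").

    Bounds are exclusive; ``None`` disables a bound. ``pct_mito`` /
    ``pct_ribo`` bounds are on the percent scale.
    """

    applies_to: str = "all"
    min_counts: float | None = None
    max_counts: float | None = None
    min_features: float | None = None
    max_features: float | None = None
    max_pct_mito: float | None = None
    max_pct_ribo: float | None = None

    def __post_init__(self) -> None:
        for lo, hi in [(self.min_counts, self.max_counts), (self.min_features, self.max_features)]:
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError(f"window bounds inverted: {lo} >= {hi}")


def compute_qc(matrix: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics: n_counts, n_features, pct_mito, pct_ribo.

    Percent metrics are 100 * (counts in flagged genes) / total; all-zero
    cells get zero metrics and ``all_zero=True``.
    """
    for col in ("is_mito", "is_ribo"):
        if col not in matrix.gene_meta.columns:
            raise ValueError(f"gene_meta lacks required flag column {col!r}")
    X = matrix.counts.tocsc()
    n_counts = np.asarray(X.sum(axis=0)).ravel()
    n_features = np.asarray((X > 0).sum(axis=0)).ravel()
    mito = np.asarray(matrix.gene_meta["is_mito"].to_numpy(), dtype=bool)
    ribo = np.asarray(matrix.gene_meta["is_ribo"].to_numpy(), dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(n_counts > 0, n_counts, 1)
        pct_mito = 100.0 * np.asarray(X[mito].sum(axis=0)).ravel() / denom
        pct_ribo = 100.0 * np.asarray(X[ribo].sum(axis=0)).ravel() / denom
    out = pd.DataFrame(
        {
            "n_counts": n_counts,
            "n_features": n_features,
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
            "all_zero": n_counts == 0,
        },
        index=pd.Index(matrix.cell_ids, name="cell_id"),
    )
    if "volume_um3" in matrix.cell_meta.columns:
        out["volume_um3"] = matrix.cell_meta["volume_um3"].to_numpy()
    if "sample" in matrix.cell_meta.columns:
        out["sample"] = matrix.cell_meta["sample"].to_numpy()
    return out


def _strictly_within(values: np.ndarray, lo, hi) -> np.ndarray:
    keep = np.ones(len(values), dtype=bool)
    if lo is not None:
        keep &= values > lo
    if hi is not None:
        keep &= values < hi
    return keep


def filter_cells(qc: pd.DataFrame, windows: list[QCWindow]) -> list[str]:
    """Kept cell ids: strictly inside every bound of the applicable window.

    Windows with ``applies_to="all"`` apply to every cell; sample-specific
    windows apply only to that sample's cells and must reference samples
    present in the table.
    """
    samples = set(qc["sample"].unique()) if "sample" in qc.columns else set()
    for w in windows:
        if w.applies_to != "all" and w.applies_to not in samples:
            raise ValueError(f"window references unknown sample {w.applies_to!r}")
    keep = np.ones(len(qc), dtype=bool)
    for w in windows:
        mask = (
            np.ones(len(qc), dtype=bool)
            if w.applies_to == "all"
            else (qc["sample"] == w.applies_to).to_numpy()
        )
        ok = _strictly_within(qc["n_counts"].to_numpy(float), w.min_counts, w.max_counts)
        ok &= _strictly_within(qc["n_features"].to_numpy(float), w.min_features, w.max_features)
        ok &= _strictly_within(qc["pct_mito"].to_numpy(float), None, w.max_pct_mito)
        ok &= _strictly_within(qc["pct_ribo"].to_numpy(float), None, w.max_pct_ribo)
        keep &= ~mask | ok
    return list(qc.index[keep])


def filter_spatial_cells(
    qc: pd.DataFrame,
    min_volume: float = 500.0,
    max_volume: float = 4000.0,
    min_transcripts: int = 40,
) -> list[str]:
    """Kept cell ids for an imaging dataset.

    Keeps cells with min_volume <= volume <= max_volume and at least
    ``min_transcripts`` detected transcripts: cells outside the volume
    window reflect segmentation failures, low-transcript cells are likely
    false detections.
    """
    if "volume_um3" not in qc.columns:
        raise ValueError("volume_um3 missing from QC table")
    vol = qc["volume_um3"].to_numpy(float)
    missing = qc.index[~np.isfinite(vol)]
    if len(missing):
        raise ValueError(f"cells missing volume: {list(missing[:10])}")
    keep = (vol >= min_volume) & (vol <= max_volume)
    keep &= qc["n_counts"].to_numpy(float) >= min_transcripts
    return list(qc.index[keep])


def infer_sex(
    matrix: CountMatrix,
    male_genes: list[str],
    female_genes: list[str],
    tau: float = 1.0,
) -> pd.DataFrame:
    """Per-cell sex call from male- vs female-specific gene counts.

    ``ratio_score = log2((male_counts + 1) / (female_counts + 1))``; a cell
    is called male iff the score is >= +tau, female iff <= -tau, otherwise
    indeterminate (both gene sets dropped out, or ambiguous). The three-way
    call mirrors the trimodal histogram such scores form in real nuclei.
    """
    if not male_genes or not female_genes:
        raise ValueError("both gene lists must be non-empty")
    m_idx = matrix.gene_index(male_genes)
    f_idx = matrix.gene_index(female_genes)
    X = matrix.counts.tocsr()
    male_counts = np.asarray(X[m_idx].sum(axis=0)).ravel()
    female_counts = np.asarray(X[f_idx].sum(axis=0)).ravel()
    score = np.log2((male_counts + 1.0) / (female_counts + 1.0))
    call = np.full(len(score), "indeterminate", dtype=object)
    call[score >= tau] = "male"
    call[score <= -tau] = "female"
    return pd.DataFrame(
        {
            "male_counts": male_counts,
            "female_counts": female_counts,
            "ratio_score": score,
            "call": call,
        },
        index=pd.Index(matrix.cell_ids, name="cell_id"),
    )


def flag_doublet_clusters(
    matrix: CountMatrix,
    labels: np.ndarray,
    marker_genes: list[str],
    frac_expressing: float = 0.5,
) -> list:
    """Clusters in which any glial marker is detected in more than
    ``frac_expressing`` of member cells — likely neuron/glia doublets.

    Markers absent from the matrix are ignored (no flag possible); empty
    clusters are an error.
    """
    labels = np.asarray(labels)
    if len(labels) != matrix.n_cells:
        raise ValueError("labels must cover all cells")
    present = [g for g in marker_genes if g in set(matrix.gene_ids)]
    uniq = pd.unique(labels)
    if any((labels == u).sum() == 0 for u in uniq):  # pragma: no cover - unreachable
        raise ValueError("empty cluster")
    if not present:
        return []
    idx = matrix.gene_index(present)
    detected = np.asarray((matrix.counts[idx] > 0).todense())  # markers x cells
    flagged = []
    for u in uniq:
        mask = labels == u
        if mask.sum() == 0:
            raise ValueError(f"empty cluster {u!r}")
        frac = detected[:, mask].mean(axis=1)
        if (frac > frac_expressing).any():
            flagged.append(u)
    return flagged
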