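"""Promoter-proximal vs distal splits and TF-density hotspot clustering.

A *transcription hotspot* is a merged region bound in a given cell type by
a large fraction of that cell type's assayed factors. The TF density of
region i in cell type c is

    density(i, c) = (# experiments of c with a peak in i) / (# experiments of c)

so values lie in [0, 1]. Clustering the M x C density matrix with k-means
separates ubiquitous hotspots (high density in every cell type — mostly
promoter-proximal) from cell-type-specific hotspots (high in one column —
mostly distal).

Proximity thresholds follow the convention: proximal = |d| < 1 kb from the
nearest TSS, distal = |d| >= 10 kb; the band in between belongs to neither
class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cooccurrence import BindingMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PROXIMAL_BP",
    "DISTAL_BP",
    "DensityMatrix",
    "HotspotClusters",
    "select_cell_types",
    "split_by_proximity",
    "proximity_class",
    "tf_density",
    "cluster_hotspots",
]

PROXIMAL_BP = 1_000
DISTAL_BP = 10_000


def select_cell_types(manifest: pd.DataFrame, min_experiments: int = 30) -> list[str]:
    """Cell types with *strictly more* than ``min_experiments`` experiments,
    sorted by experiment count descending (ties by name)."""
    counts = manifest.groupby("cell_type")["experiment_id"].count()
    sel = counts[counts > min_experiments]
    if sel.empty:
        logger.info(
            "no cell type exceeds %d experiments (max observed %s)",
            min_experiments,
            int(counts.max()) if len(counts) else 0,
        )
    # count descending, ties alphabetical (stable sort keeps index order)
    return list(sel.sort_index().sort_values(ascending=False, kind="mergesort").index)


def proximity_class(
    distances, proximal_bp: int = PROXIMAL_BP, distal_bp: int = DISTAL_BP
) -> np.ndarray:
    """Classify regions as 'proximal' (|d| < 1 kb), 'distal' (|d| >= 10 kb)
    or 'intermediate'; NaN distances class as 'unknown'."""
    d = np.abs(np.asarray(distances, dtype=float))
    out = np.full(d.shape, "intermediate", dtype=object)
    out[np.isnan(d)] = "unknown"
    out[d < proximal_bp] = "proximal"
    out[d >= distal_bp] = "distal"
    return out


def split_by_proximity(
    matrix: BindingMatrix,
    distances,
    proximal_bp: int = PROXIMAL_BP,
    distal_bp: int = DISTAL_BP,
) -> tuple[BindingMatrix, BindingMatrix]:
    """Split the binding matrix rows into promoter-proximal and distal sets.

    ``distances`` is the per-region signed nearest-TSS distance (NaN for
    regions without a TSS on their chromosome; such rows land in neither
    split). Intermediate rows (1 kb <= |d| < 10 kb) are dropped from both.
    Columns are kept as-is; all-zero columns only matter at correlation
    time.
    """
    cls = proximity_class(distances, proximal_bp, distal_bp)
    return _take_rows(matrix, cls == "proximal"), _take_rows(matrix, cls == "distal")


def _take_rows(matrix: BindingMatrix, mask: np.ndarray) -> BindingMatrix:
    return BindingMatrix(
        regions=[r for r, k in zip(matrix.regions, mask) if k],
        experiments=list(matrix.experiments),
        occupancy=matrix.occupancy[mask],
        is_reference=matrix.is_reference.copy(),
        meta=matrix.meta.copy(),
    )


@dataclass
class DensityMatrix:
    regions: list
    cell_types: list[str]
    density: np.ndarray  # (M, C) in [0, 1]
    n_experiments: dict[str, int]


def tf_density(matrix: BindingMatrix, cell_types: list[str] | None = None) -> DensityMatrix:
    """Fraction of each cell type's experiments with a peak per region.

    Reference-track columns are excluded from both numerator and
    denominator. Cell types default to all present in the matrix metadata;
    a requested cell type with zero experiments is excluded with a log line.
    """
    meta = matrix.meta.loc[~matrix.is_reference]
    occ = matrix.experiment_columns()
    if cell_types is None:
        cell_types = sorted(meta["cell_type"].unique())
    cols, counts = [], {}
    kept = []
    for ct in cell_types:
        mask = (meta["cell_type"] == ct).to_numpy()
        n = int(mask.sum())
        if n == 0:
            logger.info("cell type %s has zero experiments; excluded from density", ct)
            continue
        cols.append(occ[:, mask].sum(axis=1) / n)
        counts[ct] = n
        kept.append(ct)
    if not cols:
        raise ValueError("no cell type with experiments")
    return DensityMatrix(
        regions=list(matrix.regions),
        cell_types=kept,
        density=np.column_stack(cols),
        n_experiments=counts,
    )


@dataclass
class HotspotClusters:
    k: int
    assignment: np.ndarray  # (M,) cluster ids 0..k-1, sorted by mean density desc
    centers: np.ndarray  # (k, C)
    cell_types: list[str]
    inertia: float
    proximity_composition: pd.DataFrame | None = None  # per cluster f_up/f_tss/f_down

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(self.centers, columns=self.cell_types)
        df.insert(0, "cluster", np.arange(self.k))
        df["n_regions"] = np.bincount(self.assignment, minlength=self.k)
        df["mean_density"] = self.centers.mean(axis=1)
        return df


def cluster_hotspots(
    density: DensityMatrix,
    k: int = 6,
    seed: int = 0,
    n_init: int = 10,
    distances=None,
) -> HotspotClusters:
    """k-means clustering of the TF-density matrix.

    Lloyd iterations with k-means++ seeding from ``seed`` and ``n_init``
    restarts keeping the best inertia; deterministic given (k, seed).
    Clusters are relabelled so cluster 0 has the highest mean density
    across cell types. When per-region signed TSS distances are supplied,
    each cluster's upstream/at-TSS/downstream composition is reported
    (the top bars of the hotspot figure).
    """
    X = density.density
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] < k:
        raise ValueError(f"cannot form {k} clusters from {X.shape[0]} regions")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="mergesort")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    assignment = relabel[raw]
    centers = km.cluster_centers_[order]
    comp = None
    if distances is not None:
        d = np.asarray(distances, dtype=float)
        rows = []
        for c in range(k):
            dc = d[assignment == c]
            dc = dc[~np.isnan(dc)]
            n = max(len(dc), 1)
            rows.append(
                {
                    "cluster": c,
                    "f_up": float((dc < 0).sum() / n),
                    "f_tss": float((dc == 0).sum() / n),
                    "f_down": float((dc > 0).sum() / n),
                    "f_proximal": float((np.abs(dc) < PROXIMAL_BP).sum() / n),
                    "f_distal": float((np.abs(dc) >= DISTAL_BP).sum() / n),
                }
            )
        comp = pd.DataFrame(rows)
    return HotspotClusters(
        k=k,
        assignment=assignment,
        centers=centers,
        cell_types=list(density.cell_types),
        inertia=float(km.inertia_),
        proximity_composition=comp,
    )
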