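"""Regions × experiments binary occupancy matrix and correlation clustering.

The central object is :class:`BindingMatrix`: rows are the non-overlapping
regions obtained by merging the union of all peak sets, columns are
experiments, and a cell is 1 iff at least one peak of that experiment
shares at least one base with the region. Correlating the binary columns
(Pearson, which on 0/1 data is the phi coefficient) and hierarchically
clustering the correlation matrix reproduces the classic co-occupancy
heatmap view of a ChIP-seq compendium: a promoter cluster around RNAPII,
a tight CTCF/cohesin cluster crossing cell types, and cell-type clusters
of distal factors.

Reference tracks (e.g. TSS locations, CpG islands) can be appended as
display-only columns: they never create regions and are excluded from the
clustering itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "BindingMatrix",
    "CorrelationClustering",
    "build_matrix",
    "add_reference_track",
    "correlate",
    "cluster_correlation",
    "subset",
]


@dataclass
class BindingMatrix:
    """M merged regions × N experiments binary occupancy matrix.

    ``meta`` carries one row per column (factor/cell_type/species for
    experiments; empty strings for reference tracks).
    """

    regions: list[GenomicInterval]
    experiments: list[str]
    occupancy: np.ndarray  # (M, N) uint8
    is_reference: np.ndarray  # (N,) bool
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.uint8)
        self.is_reference = np.asarray(self.is_reference, dtype=bool)
        M, N = self.occupancy.shape
        if len(self.regions) != M or len(self.experiments) != N:
            raise ValueError("occupancy shape inconsistent with regions/experiments")
        if len(set(self.experiments)) != N:
            raise ValueError("duplicate column labels")

    @property
    def n_regions(self) -> int:
        return self.occupancy.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.occupancy[:, self.experiments.index(label)]

    def experiment_columns(self) -> np.ndarray:
        """Occupancy restricted to non-reference columns."""
        return self.occupancy[:, ~self.is_reference]

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.regions, columns=["chrom", "start", "end"])


def _mark_overlaps(
    regions: list[GenomicInterval], intervals: list[GenomicInterval]
) -> np.ndarray:
    """Boolean vector: region i True iff >=1 interval shares >=1 base with it.

    ``regions`` must be sorted and non-overlapping (merge output).
    """
    out = np.zeros(len(regions), dtype=bool)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    reg = pd.DataFrame(regions, columns=["chrom", "start", "end"])
    reg["idx"] = np.arange(len(reg))
    for chrom, sub in reg.groupby("chrom", sort=False):
        by_chrom[str(chrom)] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["idx"].to_numpy(np.int64),
        )
    for iv in intervals:
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            continue
        starts, ends, idx = entry
        # first region whose end > iv.start
        i = int(np.searchsorted(ends, iv.start, side="right"))
        while i < len(starts) and starts[i] < iv.end:
            out[idx[i]] = True
            i += 1
    return out


def build_matrix(
    manifest: pd.DataFrame, peaks: dict[str, list[GenomicInterval]]
) -> BindingMatrix:
    """Merge all peaks and build the binary occupancy matrix.

    ``peaks`` maps experiment_id to that experiment's intervals. All
    experiments must belong to one species. An experiment with zero peaks
    is kept as an all-zero column with a logged warning.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    if manifest["species"].nunique() > 1:
        raise ValueError(
            f"experiments span several species: {sorted(manifest['species'].unique())};"
            " build one matrix per species"
        )
    exp_ids = list(manifest["experiment_id"])
    all_peaks: list[GenomicInterval] = []
    for eid in exp_ids:
        ivs = peaks[eid]
        if not ivs:
            logger.warning("experiment %s has zero peaks; kept as all-zero column", eid)
        all_peaks.extend(ivs)
    regions = merge_intervals(all_peaks)
    occ = np.zeros((len(regions), len(exp_ids)), dtype=np.uint8)
    for j, eid in enumerate(exp_ids):
        occ[:, j] = _mark_overlaps(regions, peaks[eid])
    meta = manifest.set_index("experiment_id").loc[exp_ids].reset_index()
    return BindingMatrix(
        regions=regions,
        experiments=exp_ids,
        occupancy=occ,
        is_reference=np.zeros(len(exp_ids), dtype=bool),
        meta=meta,
    )


def add_reference_track(
    matrix: BindingMatrix, intervals: list[GenomicInterval], label: str
) -> BindingMatrix:
    """Append a display-only reference column (TSS, CpG islands, ...).

    The region set is unchanged — reference tracks never create regions.
    """
    if label in matrix.experiments:
        raise ValueError(f"reference-track label {label!r} collides with a column")
    col = _mark_overlaps(matrix.regions, intervals).astype(np.uint8)
    meta = pd.concat(
        [
            matrix.meta,
            pd.DataFrame(
                [{c: "" for c in matrix.meta.columns} | {"experiment_id": label}]
            ),
        ],
        ignore_index=True,
    )
    return BindingMatrix(
        regions=matrix.regions,
        experiments=matrix.experiments + [label],
        occupancy=np.hstack([matrix.occupancy, col[:, None]]),
        is_reference=np.append(matrix.is_reference, True),
        meta=meta,
    )


def correlate(matrix: BindingMatrix | np.ndarray) -> np.ndarray:
    """Pearson correlation between all column pairs of the binary matrix.

    On binary data this equals the phi coefficient. Constant columns
    (all-zero or all-one) get correlation 0 with every other column and 1
    with themselves, so no sample is dropped silently.
    """
    occ = matrix.occupancy if isinstance(matrix, BindingMatrix) else np.asarray(matrix)
    if occ.shape[1] < 2:
        raise ValueError("need >= 2 columns to correlate")
    X = occ.astype(np.float64)
    X -= X.mean(axis=0)
    norms = np.sqrt((X**2).sum(axis=0))
    constant = norms == 0
    norms[constant] = 1.0
    C = (X.T @ X) / np.outer(norms, norms)
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def _optimal_leaf_order(Z: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Exact optimal leaf ordering of a dendrogram (Bar-Joseph dynamic program).

    Finds, over all 2^(N-1) orders obtainable by flipping subtrees of the
    linkage ``Z``, the one minimising the sum of ``D`` distances between
    adjacent leaves. O(N^3) time; exact, unlike heuristic reorderings.

    The table ``M[v][i, j]`` holds the minimal internal cost of laying out
    subtree ``v`` with leftmost leaf ``i`` and rightmost leaf ``j`` (valid
    only when i and j come from different children of v).
    """
    n = D.shape[0]
    leaves: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    M: dict[int, np.ndarray] = {i: np.zeros((1, 1)) for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for idx in range(Z.shape[0]):
        v = n + idx
        l, r = int(Z[idx, 0]), int(Z[idx, 1])
        children[v] = (l, r)
        Ll, Lr = leaves[l], leaves[r]
        leaves[v] = np.concatenate([Ll, Lr])
        # tmp[i, m] = min_k M_l[i, k] + D[k, m]   (i, k over Ll; m over Lr)
        tmp = (M[l][:, :, None] + D[np.ix_(Ll, Lr)][None, :, :]).min(axis=1)
        # cost[i, j] = min_m tmp[i, m] + M_r[m, j]   (j over Lr)
        cost = (tmp[:, :, None] + M[r][None, :, :]).min(axis=1)
        a, b = len(Ll), len(Lr)
        m = np.full((a + b, a + b), np.inf)
        m[:a, a:] = cost
        m[a:, :a] = cost.T  # reversal has identical cost
        M[v] = m

    def _expand(v: int, i: int, j: int) -> list[int]:
        """Lay out subtree v with leftmost leaf i, rightmost leaf j."""
        if v < n:
            return [v]
        l, r = children[v]
        if i not in set(leaves[l].tolist()):
            l, r = r, l
        Ll, Lr = leaves[l], leaves[r]
        il = int(np.flatnonzero(Ll == i)[0])
        jr = int(np.flatnonzero(Lr == j)[0])
        inner = M[l][il, :, None] + D[np.ix_(Ll, Lr)] + M[r][:, jr][None, :]
        k, mm = np.unravel_index(np.argmin(inner), inner.shape)
        return _expand(l, i, int(Ll[k])) + _expand(r, int(Lr[mm]), j)

    root = n + Z.shape[0] - 1
    i, j = np.unravel_index(np.argmin(M[root]), M[root].shape)
    Lroot = leaves[root]
    return np.array(_expand(root, int(Lroot[i]), int(Lroot[j])), dtype=np.int64)


@dataclass
class CorrelationClustering:
    """Complete-linkage clustering of a correlation matrix with optimal leaf order."""

    labels: list[str]
    corr: np.ndarray
    linkage: np.ndarray
    leaf_order: np.ndarray  # permutation of range(N)

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def cluster_correlation(
    corr: np.ndarray, labels: list[str] | None = None, optimal_order: bool = True
) -> CorrelationClustering:
    """Cluster experiments by Euclidean distance between correlation rows.

    Complete-linkage agglomeration; leaves re-ordered by the exact optimal
    leaf ordering (minimum sum of adjacent-leaf distances consistent with
    the tree). Deterministic given the input. For very large N
    (> 2000 leaves) the ordering step is skipped with a warning and the
    plain dendrogram order is used.
    """
    corr = np.asarray(corr, dtype=np.float64)
    N = corr.shape[0]
    if N < 2:
        raise ValueError("need >= 2 experiments to cluster")
    if labels is None:
        labels = [str(i) for i in range(N)]
    # condensed Euclidean distance between rows of corr
    cond = pdist(corr, metric="euclidean")
    Z = hierarchy.linkage(cond, method="complete")
    if optimal_order and N <= 2000:
        order = _optimal_leaf_order(Z, squareform(cond))
    else:
        if optimal_order:
            logger.warning("N=%d too large for optimal leaf ordering; using plain order", N)
        order = hierarchy.leaves_list(Z)
    return CorrelationClustering(labels=list(labels), corr=corr, linkage=Z, leaf_order=order)


def cluster_matrix(matrix: BindingMatrix) -> CorrelationClustering:
    """Correlate and cluster the non-reference columns of a binding matrix."""
    keep = ~matrix.is_reference
    labels = [e for e, k in zip(matrix.experiments, keep) if k]
    corr = correlate(matrix.occupancy[:, keep])
    return cluster_correlation(corr, labels)


def subset(
    matrix: BindingMatrix,
    cell_types: list[str] | None = None,
    factors: list[str] | None = None,
) -> BindingMatrix:
    """Restrict to experiments of given cell types and/or factors.

    Reference tracks are always retained. Rows with no remaining
    non-reference occupancy are dropped (their correlations are recomputed
    downstream on the subset, matching per-panel heatmap views).
    """
    meta = matrix.meta
    keep = ~matrix.is_reference
    if cell_types is not None:
        known = set(meta.loc[~matrix.is_reference, "cell_type"])
        bad = set(cell_types) - known
        if bad:
            raise ValueError(f"unknown cell types {sorted(bad)}; valid: {sorted(known)}")
        keep &= meta["cell_type"].isin(cell_types).to_numpy()
    if factors is not None:
        known = set(meta.loc[~matrix.is_reference, "factor"])
        bad = set(factors) - known
        if bad:
            raise ValueError(f"unknown factors {sorted(bad)}; valid: {sorted(known)}")
        keep &= meta["factor"].isin(factors).to_numpy()
    if not keep.any():
        raise ValueError("selection matches no experiment")
    cols = keep | matrix.is_reference
    occ = matrix.occupancy[:, cols]
    is_ref = matrix.is_reference[cols]
    rows = occ[:, ~is_ref].any(axis=1)
    return BindingMatrix(
        regions=[r for r, k in zip(matrix.regions, rows) if k],
        experiments=[e for e, k in zip(matrix.experiments, cols) if k],
        occupancy=occ[rows],
        is_reference=is_ref,
        meta=meta.loc[cols].reset_index(drop=True),
    )
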