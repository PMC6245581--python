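"""Genomic-interval primitives: merging and strand-aware nearest-TSS annotation.

All coordinates are 0-based half-open ``[start, end)``. The two operations
here deliberately mirror the semantics of the classic genome-arithmetic
tools they replace:

* :func:`merge_intervals` collapses overlapping *and book-ended* intervals
  (``end == start``) into maximal non-overlapping regions.
* :func:`nearest_tss` annotates each region with the closest transcription
  start site and a signed distance whose sign is gene-strand relative:
  negative means the region lies upstream of the gene, positive downstream,
  and exactly 0 means the region contains the TSS base.

Distance magnitude is measured to the nearest *covered* base of the region,
i.e. ``end - 1``, not the exclusive end. For a region ``[100, 200)`` and a
TSS at 300 on ``+`` the distance is ``-(300 - 199) = -101``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "DistanceAnnotation",
    "merge_intervals",
    "nearest_tss",
]


class GenomicInterval(NamedTuple):
    """A 0-based half-open genomic interval; requires ``0 <= start < end``."""

    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class DistanceAnnotation:
    """Nearest-TSS annotation for one region.

    ``gene_id`` is ``None`` (and ``distance`` NaN) when the region's
    chromosome carries no TSS at all.
    """

    region: GenomicInterval
    gene_id: str | None
    distance: float  # signed bp; NaN when gene_id is None


def _validate(iv: GenomicInterval) -> None:
    if not (0 <= iv.start < iv.end):
        raise ValueError(f"invalid interval {iv}: need 0 <= start < end")


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse intervals into sorted, per-chromosome non-overlapping regions.

    Two inputs merge iff they overlap or are book-ended (``a.end == b.start``).
    The union of covered bases is preserved. Input may be unsorted and may
    span chromosomes.
    """
    ivs = [GenomicInterval(*iv) for iv in intervals]
    for iv in ivs:
        _validate(iv)
    ivs.sort()
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(*iv))
    return out


def _tss_arrays(tss: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (positions, gene_ids, strands), sorted by position."""
    by: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in tss.groupby("chrom", sort=False):
        sub = sub.sort_values(["pos", "gene_id"], kind="mergesort")
        by[str(chrom)] = (
            sub["pos"].to_numpy(dtype=np.int64),
            sub["gene_id"].to_numpy(dtype=object),
            sub["strand"].to_numpy(dtype=object),
        )
    return by


def _resolve_at_pos(pos: np.ndarray, genes: np.ndarray, p: int) -> str:
    """Lexicographically smallest gene id among TSSs at exactly position p."""
    lo = int(np.searchsorted(pos, p, side="left"))
    hi = int(np.searchsorted(pos, p, side="right"))
    return min(genes[lo:hi])


def nearest_tss(
    regions: Sequence[GenomicInterval], tss: pd.DataFrame
) -> list[DistanceAnnotation]:
    """Annotate each region with its closest TSS and signed distance.

    ``tss`` must have columns ``gene_id, chrom, pos, strand``. For each
    region the TSS minimising the unsigned distance wins; ties (two TSSs
    exactly equidistant) resolve to the lexicographically smaller gene id.
    Regions on chromosomes without any TSS get ``gene_id=None`` and NaN
    distance; callers exclude them from fraction computations.
    """
    by_chrom = _tss_arrays(tss)
    strand_of = {g: s for g, s in zip(tss["gene_id"], tss["strand"])}
    out: list[DistanceAnnotation] = []
    for region in regions:
        region = GenomicInterval(*region)
        _validate(region)
        entry = by_chrom.get(region.chrom)
        if entry is None:
            out.append(DistanceAnnotation(region, None, float("nan")))
            continue
        pos, genes, _strands = entry
        li = int(np.searchsorted(pos, region.start, side="left"))
        ri = int(np.searchsorted(pos, region.end, side="left"))
        if li < ri:  # at least one TSS inside [start, end)
            gene = min(genes[li:ri])
            out.append(DistanceAnnotation(region, gene, 0.0))
            continue
        # candidates: last TSS strictly left of start, first TSS >= end
        cands: list[tuple[int, int]] = []  # (unsigned distance, tss position)
        if li > 0:
            p = int(pos[li - 1])
            cands.append((region.start - p, p))
        if li < len(pos):
            p = int(pos[li])
            cands.append((p - (region.end - 1), p))
        dmin = min(c[0] for c in cands)
        best_positions = [p for d, p in cands if d == dmin]
        gene = min(_resolve_at_pos(pos, genes, p) for p in best_positions)
        # region left of the winning TSS <=> TSS position >= end
        p_best = min(
            (p for d, p in cands if d == dmin and _resolve_at_pos(pos, genes, p) == gene)
        )
        region_is_left = p_best >= region.end
        strand = strand_of[gene]
        upstream = region_is_left if strand == "+" else not region_is_left
        out.append(DistanceAnnotation(region, gene, float(-dmin if upstream else dmin)))
    return out


def annotations_to_frame(annotations: Sequence[DistanceAnnotation]) -> pd.DataFrame:
    """Tabular view of nearest-TSS annotations (one row per region)."""
    return pd.DataFrame(
        {
            "chrom": [a.region.chrom for a in annotations],
            "start": [a.region.start for a in annotations],
            "end": [a.region.end for a in annotations],
            "gene_id": [a.gene_id for a in annotations],
            "distance": [a.distance for a in annotations],
        }
    )
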