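"""Interval merging and nearest-TSS annotation against independent oracles."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from peakscape.intervals import (
    DistanceAnnotation,
    GenomicInterval,
    merge_intervals,
    nearest_tss,
)

from conftest import random_intervals, random_tss


def mask_merge_oracle(intervals, span=12_000):
    """Per-base boolean mask, then run-length extraction of covered stretches."""
    out = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        mask = np.zeros(span, dtype=bool)
        for iv in intervals:
            if iv.chrom == chrom:
                mask[iv.start : iv.end] = True
        padded = np.concatenate([[False], mask, [False]]).astype(int)
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1)
        out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def brute_nearest(region, tss):
    """Exhaustive scan over all TSSs: min unsigned distance, gene-id tie-break."""
    best = None
    for row in tss.itertuples(index=False):
        if row.chrom != region.chrom:
            continue
        if region.start <= row.pos < region.end:
            d = 0
        elif row.pos < region.start:
            d = region.start - row.pos
        else:
            d = row.pos - (region.end - 1)
        key = (d, row.gene_id)
        if best is None or key < best[0]:
            best = (key, row)
    if best is None:
        return None, float("nan")
    (d, _), row = best
    if d == 0:
        return row.gene_id, 0.0
    region_left = row.pos >= region.end
    upstream = region_left if row.strand == "+" else not region_left
    return row.gene_id, float(-d if upstream else d)


class TestMerge:
    def test_empty(self):
        assert merge_intervals([]) == []

    def test_overlap_and_bookend_chain(self):
        ivs = [
            GenomicInterval("chr1", 0, 10),
            GenomicInterval("chr1", 5, 15),
            GenomicInterval("chr1", 15, 20),
        ]
        assert merge_intervals(ivs) == [GenomicInterval("chr1", 0, 20)]

    def test_matches_base_mask_oracle(self, rng):
        for _ in range(20):
            ivs = random_intervals(rng, 1000)
            assert merge_intervals(ivs) == mask_merge_oracle(ivs)

    def test_idempotent_and_coverage_preserving(self, rng):
        ivs = random_intervals(rng, 500)
        merged = merge_intervals(ivs)
        assert merge_intervals(merged) == merged
        assert len(merged) <= len(ivs)
        # covered bases identical between input union and output
        cover_in = set()
        for iv in ivs:
            cover_in.update((iv.chrom, b) for b in range(iv.start, iv.end))
        cover_out = set()
        for iv in merged:
            cover_out.update((iv.chrom, b) for b in range(iv.start, iv.end))
        assert cover_in == cover_out

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            merge_intervals([GenomicInterval("chr1", 5, 5)])


class TestNearestTss:
    def _tss(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand"])

    def test_containment_gives_zero(self):
        tss = self._tss([("gA", "chr1", 150, "+")])
        (ann,) = nearest_tss([GenomicInterval("chr1", 100, 200)], tss)
        assert ann.gene_id == "gA" and ann.distance == 0.0

    def test_signed_distance_uses_last_covered_base(self):
        region = GenomicInterval("chr1", 100, 200)
        plus = self._tss([("gA", "chr1", 300, "+")])
        minus = self._tss([("gA", "chr1", 300, "-")])
        assert nearest_tss([region], plus)[0].distance == -101.0
        assert nearest_tss([region], minus)[0].distance == +101.0

    def test_matches_bruteforce_scan(self, rng):
        tss = random_tss(rng, 50)
        regions = random_intervals(rng, 500)
        anns = nearest_tss(regions, tss)
        for region, ann in zip(regions, anns):
            gene, d = brute_nearest(region, tss)
            assert ann.gene_id == gene
            assert ann.distance == d

    def test_translation_invariance(self, rng):
        tss = random_tss(rng, 20)
        regions = random_intervals(rng, 100)
        shift = 5_000
        tss2 = tss.assign(pos=tss["pos"] + shift)
        regions2 = [GenomicInterval(r.chrom, r.start + shift, r.end + shift) for r in regions]
        d1 = [a.distance for a in nearest_tss(regions, tss)]
        d2 = [a.distance for a in nearest_tss(regions2, tss2)]
        assert d1 == d2

    def test_strand_flip_negates_nonzero_distances(self, rng):
        tss = random_tss(rng, 30)
        regions = random_intervals(rng, 200)
        flipped = tss.assign(strand=tss["strand"].map({"+": "-", "-": "+"}))
        for a, b in zip(nearest_tss(regions, tss), nearest_tss(regions, flipped)):
            if a.distance == 0:
                assert b.distance == 0
            else:
                assert b.distance == -a.distance

    def test_chromosome_without_tss(self):
        tss = self._tss([("gA", "chr1", 100, "+")])
        anns = nearest_tss([GenomicInterval("chrX", 0, 10)], tss)
        assert anns[0].gene_id is None and np.isnan(anns[0].distance)


@pytest.mark.parametrize("seed", [0, 1])
def test_agrees_with_bedtools(tmp_path, seed):
    """Cross-check merge and signed nearest-TSS distance against bedtools."""
    rng = np.random.default_rng(seed)
    ivs = random_intervals(rng, 200, chroms=("chr1",), span=100_000)
    # distinct TSS positions so the closest gene is unique
    pos = rng.choice(np.arange(0, 100_000, 7), size=40, replace=False)
    tss = pd.DataFrame(
        {
            "gene_id": [f"g{i:02d}" for i in range(40)],
            "chrom": "chr1",
            "pos": np.sort(pos),
            "strand": rng.choice(["+", "-"], size=40),
        }
    )
    merged = merge_intervals(ivs)

    a_bed = tmp_path / "a.bed"
    b_bed = tmp_path / "b.bed"
    a_bed.write_text("".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in sorted(ivs)))
    b_bed.write_text(
        "".join(
            f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.gene_id}\t0\t{r.strand}\n"
            for r in tss.itertuples()
        )
    )
    bt_merge = subprocess.run(
        ["bedtools", "merge", "-i", str(a_bed)], capture_output=True, text=True, check=True
    ).stdout
    ours = "".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in merged)
    assert bt_merge == ours

    m_bed = tmp_path / "m.bed"
    m_bed.write_text(ours)
    bt_closest = subprocess.run(
        ["bedtools", "closest", "-a", str(m_bed), "-b", str(b_bed), "-D", "b", "-t", "first"],
        capture_output=True, text=True, check=True,
    ).stdout
    bt_dists = [int(line.split("\t")[-1]) for line in bt_closest.strip().split("\n")]
    anns = nearest_tss(merged, tss)
    assert [int(a.distance) for a in anns] == bt_dists
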