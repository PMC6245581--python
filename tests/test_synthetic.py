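"""The synthetic-data generator: determinism, genome constraints, and
recovery of every planted structure by the downstream analyses."""

import numpy as np
import pandas as pd
import pytest

from peakscape.combinations import pattern_counts
from peakscape.cooccurrence import build_matrix, correlate
from peakscape.intervals import nearest_tss
from peakscape.io import peaks_to_intervals
from peakscape.simulate import (
    GenomeSpec,
    GroundTruth,
    default_truth,
    simulate_experiments,
    simulate_genome,
    simulate_gwas,
    simulate_in_memory,
)
from peakscape.tss_preference import location_profile


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        spec = GenomeSpec(seed=5)
        t1, _ = simulate_genome(spec)
        t2, _ = simulate_genome(spec)
        pd.testing.assert_frame_equal(t1, t2)

    def test_bounds_and_spacing(self):
        spec = GenomeSpec(chrom_sizes={"chr1": 100_000}, n_genes=10, seed=1)
        tss, sizes = simulate_genome(spec)
        assert (tss["pos"] >= 0).all() and (tss["pos"] < 100_000).all()
        gaps = np.diff(np.sort(tss["pos"]))
        assert (gaps >= spec.min_spacing).all()

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(GenomeSpec(chrom_sizes={"chr1": 10_000}, n_genes=100))

    def test_strand_fraction_balanced(self):
        tss, _ = simulate_genome(GenomeSpec(seed=2))
        frac = (tss["strand"] == "+").mean()
        assert frac == pytest.approx(0.5, abs=0.05)


class TestSimulateExperiments:
    def test_reproducible_from_seed(self):
        a = simulate_in_memory(seed=4, species=("human",), scale=0.1)["human"]
        b = simulate_in_memory(seed=4, species=("human",), scale=0.1)["human"]
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        for eid in a.peaks:
            pd.testing.assert_frame_equal(a.peaks[eid], b.peaks[eid])
        pd.testing.assert_frame_equal(a.gwas, b.gwas)

    def test_generated_beds_satisfy_interval_invariants(self, small_human):
        for eid, pk in small_human.peaks.items():
            assert (pk["start"] >= 0).all()
            assert (pk["start"] < pk["end"]).all()

    def test_archetype_profiles_recovered(self, small_human):
        ds = small_human
        by_factor = {f.name: f for f in ds.truth.factors}
        for row in ds.manifest.itertuples():
            arch = by_factor[row.factor]
            if arch.co_module:
                continue  # module regions dilute the factor's own archetype
            ann = nearest_tss(peaks_to_intervals(ds.peaks[row.experiment_id]), ds.tss)
            p = location_profile([a.distance for a in ann], row.experiment_id)
            n = p.n_peaks
            tol = 4 * np.sqrt(0.25 / n) + 0.01  # binomial bound
            assert p.f_tss == pytest.approx(arch.p_tss, abs=tol)
            assert p.f_up == pytest.approx(arch.p_up, abs=tol)

    def test_replicates_correlate_above_cross_factor(self):
        ds = simulate_in_memory(seed=9, species=("human",), scale=0.2, n_replicates=2)["human"]
        sub = ds.manifest[ds.manifest["cell_type"] == "K562"].reset_index(drop=True)
        bm = build_matrix(sub, {e: peaks_to_intervals(ds.peaks[e]) for e in sub["experiment_id"]})
        C = correlate(bm)
        ids = list(bm.experiments)
        i1 = ids.index("human_K562_POLR2A")
        i2 = ids.index("human_K562_POLR2A_r2")
        within = C[i1, i2]
        cross = max(
            C[i1, j] for j, e in enumerate(ids) if "POLR2A" not in e
        )
        assert within > cross

    def test_exclusive_module_regions_recovered(self, small_human):
        ds = small_human
        mod = ds.truth.modules[0]
        ct = mod.cell_type
        sub = ds.manifest[ds.manifest["cell_type"] == ct]
        factors = sorted(sub["factor"].unique())
        fac_peaks = {
            f: [iv for e in sub.loc[sub["factor"] == f, "experiment_id"]
                for iv in peaks_to_intervals(ds.peaks[e])]
            for f in factors
        }
        mani = pd.DataFrame(
            {"experiment_id": factors, "factor": factors, "cell_type": ct,
             "species": "human", "peak_path": ""}
        )
        bm = build_matrix(mani, fac_peaks)
        counts = pattern_counts(bm.occupancy)
        mask = sum(1 << factors.index(m) for m in mod.members)
        assert counts[mask] >= 0.95 * mod.n_regions

    def test_ctcf_like_anchors_shared_across_cell_types(self, small_human):
        ds = small_human
        mani = ds.manifest.reset_index(drop=True)
        bm = build_matrix(mani, {e: peaks_to_intervals(ds.peaks[e]) for e in mani["experiment_id"]})
        C = correlate(bm)
        ids = list(bm.experiments)
        ctcf = [i for i, e in enumerate(ids) if e.endswith("_CTCF")]
        within = min(C[i, j] for i in ctcf for j in ctcf if i != j)
        cross = max(C[i, j] for i in ctcf for j in range(len(ids)) if j not in ctcf)
        assert within > cross


class TestSimulateGwas:
    def test_no_hits_gives_empty_table(self, small_human):
        ds = small_human
        truth = GroundTruth.from_json(ds.truth.to_json())
        truth.gwas_n_hits = 0
        hits = simulate_gwas(truth, ds.chrom_sizes, ds.peaks, ds.manifest)
        assert hits.empty

    def test_hits_lie_inside_genome(self, small_human):
        ds = small_human
        for chrom, sub in ds.gwas.groupby("chrom"):
            assert (sub["pos"] >= 0).all()
            assert (sub["pos"] < ds.chrom_sizes[chrom]).all()

    def test_unit_ratio_is_uniform(self, small_human):
        ds = small_human
        truth = GroundTruth.from_json(ds.truth.to_json())
        truth.gwas_enrichment = 1.0
        rng = np.random.default_rng(0)
        hits = simulate_gwas(truth, ds.chrom_sizes, ds.peaks, ds.manifest, rng=rng)
        # chromosome shares proportional to length
        share = hits.groupby("chrom").size() / len(hits)
        for chrom, s in share.items():
            assert s == pytest.approx(1 / 3, abs=0.05)


def test_truth_roundtrips_through_json():
    t = default_truth("mouse", seed=3, scale=0.5)
    back = GroundTruth.from_json(t.to_json())
    assert back == t
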