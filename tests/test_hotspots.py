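"""Proximity splits, TF-density computation and k-means hotspot clustering."""

import numpy as np
import pandas as pd
import pytest

from peakscape.cooccurrence import BindingMatrix, build_matrix
from peakscape.hotspots import (
    DensityMatrix,
    cluster_hotspots,
    select_cell_types,
    split_by_proximity,
    tf_density,
)
from peakscape.intervals import GenomicInterval

from conftest import random_intervals


def _manifest(ids, cell_types):
    return pd.DataFrame(
        {
            "experiment_id": ids,
            "factor": [f"F{i}" for i in range(len(ids))],
            "cell_type": cell_types,
            "species": "human",
            "peak_path": "",
        }
    )


class TestSelectCellTypes:
    def test_strictly_greater_than_threshold(self):
        mani = _manifest(
            [f"e{i}" for i in range(66)],
            ["A"] * 31 + ["B"] * 30 + ["C"] * 5,
        )
        assert select_cell_types(mani, 30) == ["A"]

    def test_zero_threshold_keeps_all_sorted_by_count(self):
        mani = _manifest([f"e{i}" for i in range(6)], ["B", "B", "B", "A", "A", "C"])
        assert select_cell_types(mani, 0) == ["B", "A", "C"]


class TestSplitByProximity:
    def _bm(self, n):
        regions = [GenomicInterval("chr1", 100 * i, 100 * i + 50) for i in range(n)]
        occ = np.ones((n, 1), dtype=np.uint8)
        return BindingMatrix(regions, ["e"], occ, [False],
                             _manifest(["e"], ["A"]))

    def test_boundary_conventions(self):
        bm = self._bm(5)
        # d = 0 -> proximal; -10000 -> distal (inclusive); 5000 -> neither; NaN -> neither
        prox, dist = split_by_proximity(bm, [0, -10_000, 5_000, 999, np.nan])
        assert prox.n_regions == 2  # d=0 and |d|=999
        assert dist.n_regions == 1
        assert prox.regions[0] == bm.regions[0]
        assert dist.regions[0] == bm.regions[1]

    def test_columns_retained_even_if_empty(self):
        bm = self._bm(2)
        prox, dist = split_by_proximity(bm, [0, 500])
        assert dist.n_regions == 0 and dist.experiments == ["e"]


class TestTfDensity:
    def test_counting_oracle(self, rng):
        ids = [f"e{i}" for i in range(8)]
        cts = ["A"] * 5 + ["B"] * 3
        peaks = {eid: random_intervals(rng, 40) for eid in ids}
        bm = build_matrix(_manifest(ids, cts), peaks)
        dm = tf_density(bm)
        assert dm.cell_types == ["A", "B"]
        for i in range(bm.n_regions):
            assert dm.density[i, 0] == pytest.approx(bm.occupancy[i, :5].sum() / 5)
            assert dm.density[i, 1] == pytest.approx(bm.occupancy[i, 5:].sum() / 3)
        # conservation: sum_i density * n_experiments == total occupancy events
        events_a = dm.density[:, 0].sum() * 5
        assert events_a == pytest.approx(bm.occupancy[:, :5].sum())

    def test_extremes(self):
        regions = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]
        occ = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        bm = BindingMatrix(regions, ["a", "b"], occ, [False, False],
                           _manifest(["a", "b"], ["A", "A"]))
        dm = tf_density(bm)
        assert dm.density[0, 0] == 1.0 and dm.density[1, 0] == 0.0

    def test_reference_columns_excluded(self, rng):
        ids = ["a", "b"]
        peaks = {eid: random_intervals(rng, 30) for eid in ids}
        bm = build_matrix(_manifest(ids, ["A", "A"]), peaks)
        from peakscape.cooccurrence import add_reference_track

        bm2 = add_reference_track(
            bm, [GenomicInterval(r.chrom, r.start, r.end) for r in bm.regions], "TSS"
        )
        assert np.array_equal(tf_density(bm2).density, tf_density(bm).density)


class TestClusterHotspots:
    def test_recovers_planted_blocks(self):
        rngl = np.random.default_rng(5)
        hi = 0.9 + 0.02 * rngl.standard_normal((60, 3))
        lo = 0.05 + 0.02 * rngl.standard_normal((140, 3))
        dm = DensityMatrix(regions=[None] * 200, cell_types=["a", "b", "c"],
                           density=np.vstack([hi, lo]), n_experiments={})
        hc = cluster_hotspots(dm, k=2, seed=0)
        # cluster 0 is the dense block (labels sorted by mean density)
        assert (hc.assignment[:60] == 0).all()
        assert (hc.assignment[60:] == 1).all()

    def test_k_equal_m_gives_zero_inertia(self):
        X = np.arange(12, dtype=float).reshape(6, 2) / 12
        dm = DensityMatrix([None] * 6, ["a", "b"], X, {})
        hc = cluster_hotspots(dm, k=6, seed=0)
        assert hc.inertia == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed_and_near_optimal(self):
        rngl = np.random.default_rng(7)
        X = rngl.uniform(size=(200, 3))
        dm = DensityMatrix([None] * 200, ["a", "b", "c"], X, {})
        h1 = cluster_hotspots(dm, k=4, seed=3)
        h2 = cluster_hotspots(dm, k=4, seed=3)
        assert np.array_equal(h1.assignment, h2.assignment)
        # inertia within 1% of the best of many random restarts
        best = cluster_hotspots(dm, k=4, seed=1, n_init=100).inertia
        assert h1.inertia <= best * 1.01

    def test_invalid_k_rejected(self):
        dm = DensityMatrix([None] * 3, ["a"], np.zeros((3, 1)), {})
        with pytest.raises(ValueError):
            cluster_hotspots(dm, k=5, seed=0)

    def test_proximity_composition(self):
        X = np.vstack([np.full((50, 2), 0.9), np.full((50, 2), 0.1)])
        d = np.array([0] * 50 + [20_000] * 50, dtype=float)
        dm = DensityMatrix([None] * 100, ["a", "b"], X, {})
        hc = cluster_hotspots(dm, k=2, seed=0, distances=d)
        comp = hc.proximity_composition.set_index("cluster")
        assert comp.loc[0, "f_proximal"] == 1.0
        assert comp.loc[1, "f_distal"] == 1.0
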