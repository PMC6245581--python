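"""Binding-matrix construction, phi correlation, and clustering with optimal
leaf order, each against closed-form or exhaustive oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from peakscape.cooccurrence import (
    BindingMatrix,
    add_reference_track,
    build_matrix,
    cluster_correlation,
    correlate,
    subset,
)
from peakscape.intervals import GenomicInterval

from conftest import random_intervals


def _manifest(ids, cell_types=None, factors=None):
    n = len(ids)
    return pd.DataFrame(
        {
            "experiment_id": ids,
            "factor": factors or [f"F{i}" for i in range(n)],
            "cell_type": cell_types or ["CT"] * n,
            "species": "human",
            "peak_path": "",
        }
    )


def phi_oracle(x, y):
    """Closed-form phi coefficient (M*n11 - n1*n2)/sqrt(n1(M-n1)n2(M-n2))."""
    M = len(x)
    n1, n2 = int(x.sum()), int(y.sum())
    n11 = int((x & y).sum())
    denom = np.sqrt(float(n1) * (M - n1) * n2 * (M - n2))
    return (M * n11 - n1 * n2) / denom


class TestBuildMatrix:
    def test_single_experiment_disjoint_peaks(self):
        peaks = {"e1": [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30),
                        GenomicInterval("chr2", 0, 5)]}
        bm = build_matrix(_manifest(["e1"]), peaks)
        assert bm.occupancy.shape == (3, 1)
        assert bm.occupancy.all()

    def test_identical_peak_files_give_identical_columns(self, rng):
        ivs = random_intervals(rng, 50)
        bm = build_matrix(_manifest(["a", "b"]), {"a": ivs, "b": list(ivs)})
        assert (bm.occupancy[:, 0] == bm.occupancy[:, 1]).all()

    def test_matches_bruteforce_overlap_scan(self, rng):
        ids = [f"e{i}" for i in range(5)]
        peaks = {eid: random_intervals(rng, 60) for eid in ids}
        bm = build_matrix(_manifest(ids), peaks)
        for i, region in enumerate(bm.regions):
            for j, eid in enumerate(ids):
                expect = any(
                    iv.chrom == region.chrom and iv.start < region.end and iv.end > region.start
                    for iv in peaks[eid]
                )
                assert bool(bm.occupancy[i, j]) == expect
        # every region touched by at least one experiment
        assert bm.occupancy.any(axis=1).all()

    def test_zero_peak_experiment_kept_as_zero_column(self, rng):
        peaks = {"a": random_intervals(rng, 20), "b": []}
        bm = build_matrix(_manifest(["a", "b"]), peaks)
        assert bm.occupancy[:, 1].sum() == 0

    def test_mixed_species_rejected(self, rng):
        mani = _manifest(["a", "b"])
        mani.loc[1, "species"] = "mouse"
        with pytest.raises(ValueError, match="species"):
            build_matrix(mani, {"a": random_intervals(rng, 5), "b": random_intervals(rng, 5)})


class TestReferenceTrack:
    def test_track_overlap_and_label_collision(self, rng):
        peaks = {"a": random_intervals(rng, 40)}
        bm = build_matrix(_manifest(["a"]), peaks)
        # every region contains one of its own covered points -> all ones
        pts = [GenomicInterval(r.chrom, r.start, r.start + 1) for r in bm.regions]
        bm2 = add_reference_track(bm, pts, "TSS")
        assert bm2.column("TSS").all() and bm2.is_reference[-1]
        assert bm2.n_regions == bm.n_regions
        empty = add_reference_track(bm, [], "empty")
        assert empty.column("empty").sum() == 0
        with pytest.raises(ValueError):
            add_reference_track(bm, pts, "a")

    def test_track_matches_bruteforce(self, rng):
        peaks = {"a": random_intervals(rng, 60), "b": random_intervals(rng, 60)}
        bm = build_matrix(_manifest(["a", "b"]), peaks)
        track = random_intervals(rng, 30)
        bm2 = add_reference_track(bm, track, "cpg")
        for i, region in enumerate(bm2.regions):
            expect = any(
                iv.chrom == region.chrom and iv.start < region.end and iv.end > region.start
                for iv in track
            )
            assert bool(bm2.column("cpg")[i]) == expect


class TestCorrelate:
    def test_identical_and_complementary_columns(self):
        x = np.array([1, 0, 1, 0, 1], dtype=np.uint8)
        occ = np.column_stack([x, x, 1 - x])
        C = correlate(occ)
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(-1.0)

    def test_matches_phi_closed_form(self, rng):
        occ = (rng.random((100, 4)) < rng.uniform(0.2, 0.8, size=4)).astype(np.uint8)
        C = correlate(occ)
        for i, j in itertools.combinations(range(4), 2):
            assert C[i, j] == pytest.approx(phi_oracle(occ[:, i], occ[:, j]), abs=1e-12)

    def test_constant_column_rule(self):
        occ = np.array([[1, 1], [1, 0], [1, 1]], dtype=np.uint8)
        C = correlate(occ)
        assert C[0, 0] == 1.0 and C[0, 1] == 0.0 and C[1, 0] == 0.0

    def test_column_permutation_equivariance(self, rng):
        occ = (rng.random((60, 5)) < 0.4).astype(np.uint8)
        perm = rng.permutation(5)
        C = correlate(occ)
        Cp = correlate(occ[:, perm])
        assert np.allclose(Cp, C[np.ix_(perm, perm)])


def enumerate_tree_orders(Z, n):
    """All leaf orders consistent with a linkage tree (every subtree flip)."""

    def orders(node):
        if node < n:
            return [[node]]
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        out = []
        for lo in orders(left):
            for ro in orders(right):
                out.append(lo + ro)
                out.append(ro + lo)
        return out

    return orders(2 * n - 2)


def adjacent_distance_sum(order, D):
    return sum(D[a, b] for a, b in zip(order[:-1], order[1:]))


class TestClusterCorrelation:
    def test_duplicate_pairs_adjacent(self, rng):
        occ = (rng.random((80, 2)) < 0.5).astype(np.uint8)
        occ = np.column_stack([occ[:, 0], occ[:, 1], occ[:, 0], occ[:, 1]])
        cl = cluster_correlation(correlate(occ), labels=["a1", "b1", "a2", "b2"])
        order = cl.ordered_labels()
        assert abs(order.index("a1") - order.index("a2")) == 1
        assert abs(order.index("b1") - order.index("b2")) == 1

    def test_outlier_merges_last(self):
        # three mutually similar rows and one far outlier
        corr = np.array(
            [
                [1.0, 0.9, 0.8, -0.9],
                [0.9, 1.0, 0.85, -0.8],
                [0.8, 0.85, 1.0, -0.85],
                [-0.9, -0.8, -0.85, 1.0],
            ]
        )
        cl = cluster_correlation(corr)
        # the root merge of the linkage joins the outlier with the rest
        last = cl.linkage[-1]
        sizes = {int(last[0]), int(last[1])}
        assert 3 in sizes  # leaf index 3 is one side of the final merge

    @pytest.mark.parametrize("n", [5, 7, 8])
    def test_leaf_order_is_exhaustively_optimal(self, n, rng):
        corr = correlate((rng.random((60, n)) < 0.5).astype(np.uint8))
        cl = cluster_correlation(corr)
        D = np.sqrt(((corr[:, None, :] - corr[None, :, :]) ** 2).sum(-1))
        ours = adjacent_distance_sum(list(cl.leaf_order), D)
        best = min(
            adjacent_distance_sum(o, D) for o in enumerate_tree_orders(cl.linkage, n)
        )
        assert ours == pytest.approx(best, abs=1e-9)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            cluster_correlation(np.array([[1.0]]))


class TestSubset:
    def _bm(self, rng):
        ids = ["a_ct1", "b_ct1", "c_ct2", "d_ct2"]
        mani = _manifest(ids, cell_types=["ct1", "ct1", "ct2", "ct2"],
                         factors=["A", "B", "A", "D"])
        peaks = {eid: random_intervals(rng, 30) for eid in ids}
        return build_matrix(mani, peaks), peaks

    def test_identity_subset(self, rng):
        bm, _ = self._bm(rng)
        sb = subset(bm, cell_types=["ct1", "ct2"])
        assert sb.experiments == bm.experiments
        assert np.array_equal(sb.occupancy, bm.occupancy)

    def test_single_cell_type_drops_unbound_rows(self, rng):
        bm, _ = self._bm(rng)
        sb = subset(bm, cell_types=["ct1"])
        assert sb.experiments == ["a_ct1", "b_ct1"]
        expected_rows = int(bm.occupancy[:, :2].any(axis=1).sum())
        assert sb.n_regions == expected_rows
        assert sb.occupancy.any(axis=1).all()

    def test_unknown_selection_rejected(self, rng):
        bm, _ = self._bm(rng)
        with pytest.raises(ValueError, match="valid"):
            subset(bm, factors=["NOPE"])
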