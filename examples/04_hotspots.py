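"""Transcription-factor hotspots: proximal/distal splits and density clusters.

Splits merged regions into promoter-proximal (|d| < 1 kb) and distal
(|d| >= 10 kb) sets, contrasts the co-occupancy correlation in the two
compartments, then k-means-clusters the per-cell-type TF density matrix
(fraction of a cell type's experiments bound per region) to separate
ubiquitous promoter hotspots from cell-type-specific distal ones.
"""

import numpy as np

from peakscape.cooccurrence import build_matrix, correlate
from peakscape.hotspots import cluster_hotspots, split_by_proximity, tf_density
from peakscape.intervals import nearest_tss
from peakscape.io import peaks_to_intervals
from peakscape.simulate import simulate_in_memory

ds = simulate_in_memory(seed=1, species=("human",), scale=0.3)["human"]
mani = ds.manifest.reset_index(drop=True)
bm = build_matrix(mani, {e: peaks_to_intervals(ds.peaks[e]) for e in mani["experiment_id"]})

dists = np.array([a.distance for a in nearest_tss(bm.regions, ds.tss)])
prox, dist = split_by_proximity(bm, dists)
print(f"{bm.n_regions} regions: {prox.n_regions} proximal (<1 kb), "
      f"{dist.n_regions} distal (>=10 kb)")

n = len(bm.experiments)
off = ~np.eye(n, dtype=bool)
print(f"mean off-diagonal correlation: proximal {correlate(prox)[off].mean():+.3f}, "
      f"distal {correlate(dist)[off].mean():+.3f}")
print("-> promoter-proximal binding is shared; distal binding is cell-specific.\n")

dm = tf_density(bm)
hc = cluster_hotspots(dm, k=5, seed=0, distances=dists)
print("k-means clusters of TF density (cluster 0 = densest):")
print(hc.summary().round(3).to_string(index=False))
comp = hc.proximity_composition
print("\nper-cluster proximity composition:")
print(comp.round(3).to_string(index=False))
print("\n-> the cluster dense in ALL cell types has the highest promoter-")
print("   proximal fraction; one-cell-type clusters are mostly distal.")
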