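"""Combinatorial co-binding: exact pattern enrichment vs a permutation null.

For one cell type, every region bound by >= 1 factor carries an exact
binding pattern (the precise factor subset binding it). Observed pattern
counts are compared against 100 randomized matrices in which each factor
column is independently permuted (its number of binding events preserved).
The planted Oct4/Sox2/Nanog-style exclusive module is recovered as the
top co-binding pattern with an astronomical z-score.
"""

import pandas as pd

from peakscape.combinations import cell_type_enrichment, select_combinatorial_cell_types
from peakscape.cooccurrence import build_matrix
from peakscape.io import peaks_to_intervals
from peakscape.simulate import simulate_in_memory

ds = simulate_in_memory(seed=1, species=("human",), scale=0.3)["human"]
mani = ds.manifest.reset_index(drop=True)

cts = select_combinatorial_cell_types(mani, min_factors=6)
print(f"cell types with >= 6 factors: {cts}")

ct = ds.truth.modules[0].cell_type  # the cell type carrying the planted module
sub = mani[mani["cell_type"] == ct]
factors = sorted(sub["factor"].unique())
fac_peaks = {
    f: [iv for e in sub.loc[sub["factor"] == f, "experiment_id"]
        for iv in peaks_to_intervals(ds.peaks[e])]
    for f in factors
}
fac_mani = pd.DataFrame(
    {"experiment_id": factors, "factor": factors, "cell_type": ct,
     "species": "human", "peak_path": ""}
)
bm = build_matrix(fac_mani, fac_peaks)
res = cell_type_enrichment(bm.occupancy, factors, n_rand=100, seed=0)

print(f"\n{ct}: {bm.n_regions} bound regions, {len(factors)} factors, "
      f"{2 ** len(factors) - 1} possible patterns")
cob = res[res["n_factors"] >= 2].head(5)
print("\ntop co-binding patterns (observed vs randomization null):")
print(cob[["pattern_name", "observed", "null_mean", "null_sd", "z", "p_bonf"]]
      .round(2).to_string(index=False))
print("\n-> the planted exclusive triple tops the list: its loci are bound")
print("   by exactly those three factors far more often than chance allows.")
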