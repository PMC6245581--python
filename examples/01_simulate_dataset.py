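"""Generate a synthetic two-species ChIP-seq compendium with planted truth.

Builds a small genome per species, places peaks for factors with distinct
TSS-proximity archetypes (promoter-biased, CTCF-like shared distal,
cell-type-specific distal, downstream- and upstream-biased), plants an
exclusive Oct4/Sox2/Nanog-style co-binding module and a GWAS-enriched
factor, and writes all artifacts (manifest, BEDs, TSS tables, GWAS
catalog, ground-truth JSON) to disk.
"""

from pathlib import Path

from peakscape.simulate import simulate_dataset

outdir = Path("example_output/simulate")
paths = simulate_dataset(outdir, seed=1, scale=0.3)

print(f"wrote dataset under {outdir}")
for key in ("manifest", "truth", "tss_human", "gwas_human"):
    print(f"  {key:10s} -> {paths[key]}")

manifest = (outdir / "manifest.tsv").read_text().splitlines()
print(f"\n{len(manifest) - 1} experiments; first three rows:")
for line in manifest[:4]:
    print("  " + line)
print("\nEach experiment is one (factor, cell type) peak BED; truth.json")
print("records the planted archetypes, co-binding module and GWAS factor")
print("so downstream analyses can be checked against ground truth.")
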