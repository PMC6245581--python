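# Methods

This note documents the models and procedures implemented in `peakscape`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinates and interval semantics

All coordinates are 0-based half-open `[start, end)`. Zero-length
intervals are rejected at parse time: a peak is a non-empty region, and
admitting `start == end` would make overlap semantics ambiguous.
Chromosome names are normalized on input (`"1" → "chr1"`, mitochondrial
aliases `MT`/`M` → `chrM` via a fixed table). GWAS catalog positions are
1-based in the file dialect and converted on read.

**Merging.** Two intervals merge iff they overlap or are book-ended
(`a.end == b.start`), matching the default behaviour of the standard
genome-arithmetic tools, so the merged-region granularity is the familiar
one. Merging is idempotent and preserves the union of covered bases.

**Nearest-TSS distance.** The unsigned distance from a region to a TSS at
position `p` is 0 when `start ≤ p < end`, else
`min(|p − start|, |p − (end−1)|)` — measured to the nearest *covered*
base, not the exclusive end. The sign is gene-strand relative: negative
means the region lies upstream of the gene, positive downstream. (For a
TSS stored as the point interval `[p, p+1)` this convention coincides
exactly, magnitude and sign, with `bedtools closest -D b`; the test suite
cross-checks this.) Ties between equidistant TSSs resolve to the
lexicographically smaller gene id, which makes the annotation
deterministic. Regions on chromosomes without any TSS are annotated with
a null gene and excluded from all fraction computations.

**Median TSS.** A gene with several transcript start sites is collapsed
to the median position; for an even transcript count the *lower* middle
value is taken so the collapsed TSS stays on an observed transcript
start. Minus-strand transcripts contribute their last covered base
(`end − 1`).

## Co-occupancy matrix and clustering

A cell of the regions × experiments matrix is 1 iff at least one peak of
the experiment shares at least one base with the region; no
minimum-overlap-fraction rule is applied. An experiment with zero peaks
is kept as an all-zero column (with a warning) rather than silently
dropped; constant columns are assigned correlation 0 with every other
column and 1 with themselves so the matrix stays finite. Reference tracks
(TSS positions, optionally CpG islands) are display-only columns: they
never create regions and are excluded from clustering, density and
enrichment computations.

Experiments are clustered by complete linkage on the Euclidean distances
between rows of the correlation matrix. Leaf order is the *exact*
optimum: the dynamic program over subtree orientations (Bar-Joseph
optimal leaf ordering) that minimises the sum of distances between
adjacent leaves over all 2^(N−1) tree-consistent orders. The scipy
reordering routine was found not to attain this minimum on small
complete-linkage instances (tree-consistent orders with strictly smaller
adjacent-distance sums exist), so the DP is implemented here and verified
against exhaustive enumeration for N ≤ 8. It is O(N³); above N = 2000 the
package falls back to plain dendrogram order with a warning.

## Location profiles

Per experiment, `f_tss`, `f_up`, `f_down` are the fractions of peaks with
`d = 0`, `d < 0`, `d > 0`; peaks with undefined distance are excluded. An
experiment is upstream-biased iff `f_up > 0.5` (RNA-polymerase-III-like),
downstream-biased iff `f_down > 0.5` (ZNF274-like), else balanced; the
balanced continuum is displayed sorted by `f_tss` descending. Factors are
matched across species case-insensitively (`CFOS ≡ cFos`); a collision
after case-normalization is an error rather than a silent merge. The
spread bar per factor is the unscaled median absolute deviation (no
1.4826 consistency factor — it is a display range, not a σ estimate).
The regression is ordinary least squares of the second species' per-factor
medians on the first's; inconsistent replicates are reported, not
resolved.

## Proximity classes and hotspot density

Promoter-proximal means `|d| < 1,000` bp; distal means `|d| ≥ 10,000` bp
(boundary inclusive). The band between 1 and 10 kb belongs to neither
class, so proximal + distal region counts deliberately undercount the
universe. TF density is
`density(i, c) = (# experiments of cell type c binding region i) / (# experiments of c)`,
computed only for cell types passing the experiment-count threshold
(default: strictly more than 30 experiments; synthetic runs lower this to
5 since the default generated study has 6–9 experiments per cell type).
Density matrices are clustered with k-means (k-means++ seeding, 10
restarts keeping best inertia, mandatory seed; deterministic given
(k, seed)). k is not identified by the data and defaults to 6; clusters
are relabelled by mean density descending so "cluster 0" is always the
densest. Each cluster's upstream/at-TSS/downstream and proximal/distal
composition is reported alongside its per-cell-type centre.

## Combinatorial co-binding

Within one cell type, replicates of a factor are collapsed by peak-set
union; the universe is the merged regions bound by ≥ 1 of the cell type's
factors; each region contributes to exactly one pattern — the exact
factor subset binding it. The null ensemble (default 100 draws)
independently permutes each column of the matrix, preserving every
factor's binding-event count exactly (asserted per draw); rows that
become all-zero in a draw tally as the empty pattern and never enter the
family. For N = 2 this null is analytically Hypergeometric(M, n₁, n₂) in
the co-occurrence count, which the tests use as an independent oracle for
the whole machinery.

p-values come from the standard-normal upper tail of
`z = (observed − null mean)/null sd`, not from the empirical rank: a
100-draw empirical p is floored at 1/101, while genuinely co-bound factor
pairs produce z in the hundreds; the normal tail is the minimal reading
that can express such significances. Degenerate patterns (null sd = 0)
get p = 1 when observed equals the null mean and p = 0 with a degeneracy
flag otherwise. Bonferroni multiplies by all 2^N − 1 non-empty patterns,
observed or not. Only enrichment is tested; depletion is out of scope.
Cell types qualify with ≥ 6 distinct factors (configurable).

**Calibration is a matrix-level guarantee.** The null conditions on the
discovered-region universe (only bound regions exist as rows). When
factors bind truly independently *as peaks on a genome*, coincidental
co-localization is rarer than that conditioned null expects, so
single-factor ("binds alone") patterns come out enriched even without
planted structure — visibly so for factors with private region sets,
e.g. CTCF-alone patterns in realistic runs. Family-wise false-flag
control (≤ 5% of patterns at Bonferroni 0.05) holds, and is tested, when
the data-generating process is the one the null models: columns drawn as
uniform random subsets of a fixed region universe. Interpretation of
single-factor patterns on real data should keep this conditioning in
mind; multi-factor co-binding patterns are the analysis target.

## GWAS overlap

The universe U is the dataset's merged-region set, counted at region
level; K regions contain ≥ 1 catalog hit (a point, optionally extended by
a symmetric window, default 0; LD expansion is out of scope). Each
experiment's n bound regions with k marked are scored by
`P(X ≥ k), X ~ HG(U, K, n)`, assembled from log-gamma terms with
log-space tail accumulation so tails far below double-precision underflow
of individual pmf terms remain accurate (verified against exact integer
summation to 1e−12 relative for all U ≤ 60). Bonferroni is over the
number of experiments tested. A region with several hits counts once for
the test but keeps its full trait set for the per-trait breakdown.

Known limitation: hits uniform *per base pair* mark wide regions more
often, so experiments binding wide (typically promoter) merged regions
show mild enrichment under the region-level test — a width confounder
inherent to counting at region granularity. The planted-enrichment
recovery tests therefore plant the signal in a factor with private distal
regions and assert that factor is flagged and top-ranked.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
not the sequencing process: no reads, no peak calling, no signal values.

* **Genome**: 3 chromosomes × 10 Mb, 1,000 genes, TSS positions uniform
  subject to ≥ 2 kb spacing, strands Bernoulli(1/2).
* **Peaks**: widths log-normal (median 300 bp, σ_log 0.4, floor 50 bp),
  typical of TF ChIP-seq peak calls. A peak is placed relative to a
  uniformly chosen gene: TSS-category peaks are centred on the TSS;
  distal peaks are offset log-uniformly in [1 kb, 100 kb] on the
  strand-appropriate side so both the 1 kb and 10 kb thresholds are
  exercised. Offsets are clamped to half the gap to the neighbouring TSS,
  which guarantees the planted gene stays the nearest TSS — this is what
  makes archetype fractions recoverable to ± 0.02 at depth rather than
  only approximately.
* **Archetypes** (defaults): promoter factors (`p_tss` 0.7–0.8,
  RNAPII/BRCA1-like), a CTCF-like `distal_shared` factor whose single
  anchor set is reused (95% resampled) in every cell type, two
  `distal_cell_specific` factors per cell type drawing 80% of their
  distal peaks from a per-cell-type shared enhancer pool (so same-cell
  distal factors co-cluster and different-cell ones do not), one private
  cell-specific factor carrying the planted GWAS enrichment, a
  downstream-biased factor (`f_down` 0.6, ZNF274-like) and an
  upstream-biased one (`f_up` 0.6, RNA-Pol-III-like).
* **Planted module**: 1,000 regions bound by exactly Oct4/Sox2/Nanog-like
  members in the ES-like cell type. Exclusivity is enforced by rejection
  sampling with a 1 bp margin, so no foreign peak can overlap *or
  book-end* (and thus merge into) a module region; recovery of the exact
  triple count is therefore essentially lossless.
* **GWAS catalog**: with planted-factor coverage fraction c and target
  per-bp rate ratio r, each hit falls inside the factor's peak union with
  probability `q = c(r−1)/(1+c(r−1))` (length-weighted, uniform within)
  and uniformly over the genome otherwise, giving an inside/outside rate
  ratio of exactly r; r = 1 degenerates to a uniform catalog. Traits come
  from a small fixed vocabulary.
* **Scale**: defaults give ~36 experiments (9–11 factors × 2–3 cell
  types × 2 species) and ~15,000 merged regions per species — the full
  pipeline runs in well under a minute on one CPU. A `scale` multiplier
  shrinks peak counts proportionally for tests. Everything is
  reproducible from (seed, ground truth), and the ground truth is
  serialized as JSON next to the data.

What passing tests on this generator show: the pipeline recovers planted
co-occupancy structure, location archetypes, hotspot geography,
co-binding modules and GWAS enrichment from peak files with the right
marginal statistics. What they do not show: robustness to peak-caller
artefacts, signal-strength variation, mappability/GC structure, LD
between GWAS hits, or annotation disagreements between species — none of
which the generator emulates.

## Pipeline

Stages (`matrix → heatmap → tss → hotspots → combos → gwas`) communicate
only through on-disk artifacts (BED, TSV, MatrixMarket, JSON), each
validating its upstream inputs and naming the stage to run first when one
is missing. All thresholds live in one flat `key=value` config
(`proximal_bp=1000`, `distal_bp=10000`,
`min_experiments_per_cell_type=30`, `min_factors_combinatorial=6`,
`n_rand=100`, `kmeans_k=6`, `alpha=0.05`, `gwas_window=0`, `seed`);
every run echoes the fully-resolved config next to its outputs. Per-stage
seeds are derived from the master seed by hashing the stage name, so
stages are independently reproducible and identically-seeded runs are
byte-identical in their text artifacts (heatmap images are rendered for
inspection, not compared).
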