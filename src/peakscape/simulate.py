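"""Synthetic ChIP-seq compendium generator with planted ground truth.

Emulates, at desk scale, the statistical structure every pipeline stage
assumes about a real peak compendium:

* a small genome (default 3 chromosomes x 10 Mb) with ~1,000 genes whose
  TSSs are uniformly placed subject to a minimum spacing;
* factors with distinct TSS-proximity archetypes — promoter-biased
  (RNAPII-like, f_tss ~ 0.8), distal (CTCF/enhancer-like, f_tss < 0.2),
  downstream-biased (ZNF274-like, > 50% of peaks 3' of the TSS) and
  upstream-biased (RNA-polymerase-III-like);
* a CTCF-like factor whose peak set is one fixed anchor list reused in
  every cell type (the cross-cell-type cohesin cluster);
* cell-type-specific distal factors drawing from a per-cell-type shared
  "enhancer pool" (so same-cell distal factors co-cluster, different-cell
  ones do not);
* a planted co-binding module: a set of regions bound by exactly a given
  factor subset and nothing else (Oct4/Sox2/Nanog-style), enforced by
  rejection sampling with a 1 bp margin so no foreign peak can merge into
  a module region;
* a planted GWAS-enriched factor whose peak regions receive trait hits at
  a chosen per-base-pair rate ratio over the genomic background.

Every dataset is reproducible from (seed, ground truth); the ground truth
is serialized as JSON next to the generated files for recovery tests.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left, insort
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio

__all__ = [
    "GenomeSpec",
    "FactorArchetype",
    "CoModule",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_experiments",
    "simulate_gwas",
    "default_truth",
    "simulate_in_memory",
    "simulate_dataset",
]

TRAIT_VOCABULARY = [
    "breast carcinoma",
    "inflammatory bowel disease",
    "type 2 diabetes",
    "childhood obesity",
    "coronary artery disease",
    "rheumatoid arthritis",
    "schizophrenia",
    "height",
]

MIN_DISTAL_OFFSET = 1_000
MAX_DISTAL_OFFSET = 100_000


@dataclass
class GenomeSpec:
    """Synthetic genome layout; TSS spacing >= ``min_spacing`` is enforced."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    )
    n_genes: int = 1000
    min_spacing: int = 2_000
    seed: int = 0


@dataclass
class FactorArchetype:
    """Location-preference archetype of one factor.

    ``kind`` is one of ``promoter``, ``distal_shared``,
    ``distal_cell_specific``, ``downstream_biased``, ``upstream_biased``.
    ``pool_share`` (cell-specific factors only) is the fraction of distal
    peaks drawn from the cell type's shared enhancer pool; it assumes
    ``p_up == p_down`` because pool anchors are side-balanced. ``n_peaks``
    counts the factor's own peaks, excluding planted co-module regions.
    ``cell_types`` limits where the factor is assayed (None = everywhere).
    """

    name: str
    kind: str
    p_tss: float
    p_up: float
    p_down: float
    n_peaks: int = 1000
    width_median: float = 300.0
    width_sigma_log: float = 0.4
    pool_share: float = 0.0
    co_module: str | None = None
    cell_types: list[str] | None = None

    def __post_init__(self) -> None:
        if abs(self.p_tss + self.p_up + self.p_down - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: p_tss + p_up + p_down must be 1")
        if self.n_peaks < 1:
            raise ValueError(f"{self.name}: n_peaks must be >= 1")


@dataclass
class CoModule:
    """Planted exact co-binding module: ``n_regions`` loci bound by exactly
    the member factors (and nothing else when ``exclusive``)."""

    module_id: str
    members: list[str]
    cell_type: str
    n_regions: int = 1000
    exclusive: bool = True


@dataclass
class GroundTruth:
    """Everything needed to regenerate and audit one species' dataset."""

    species: str
    cell_types: list[str]
    factors: list[FactorArchetype]
    modules: list[CoModule]
    gwas_factor: str
    gwas_enrichment: float = 3.0
    gwas_n_hits: int = 2000
    enhancer_pool_size: int = 1500
    shared_resample: float = 0.95
    replicate_resample: float = 0.9
    seed: int = 0

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["factors"] = [FactorArchetype(**f) for f in d["factors"]]
        d["modules"] = [CoModule(**m) for m in d["modules"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(spec: GenomeSpec) -> tuple[pd.DataFrame, dict[str, int]]:
    """Draw the TSS table: positions uniform per chromosome subject to the
    minimum spacing, strands Bernoulli(1/2); deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.chrom_sizes
    total = sum(sizes.values())
    rows = []
    gid = 0
    # apportion genes to chromosomes proportionally to length
    names = list(sizes)
    counts = [int(round(spec.n_genes * sizes[c] / total)) for c in names]
    counts[-1] += spec.n_genes - sum(counts)
    for chrom, n_c in zip(names, counts):
        L = sizes[chrom]
        slack = L - (n_c - 1) * spec.min_spacing - 1
        if slack <= 0:
            raise ValueError(
                f"cannot place {n_c} TSS with spacing {spec.min_spacing} on {chrom} ({L} bp)"
            )
        u = np.sort(rng.uniform(0, slack, size=n_c))
        pos = (u + np.arange(n_c) * spec.min_spacing).astype(np.int64)
        strands = rng.choice(["+", "-"], size=n_c)
        for p, s in zip(pos, strands):
            rows.append((f"g{gid:05d}", chrom, int(p), str(s)))
            gid += 1
    tss = pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand"])
    return tss, dict(sizes)


# ---------------------------------------------------------------------------
# Placement machinery


class _Registry:
    """Per-chromosome store of disjoint intervals with overlap queries.

    Used for rejection sampling: module regions and 'structured' region
    sets (shared anchors, enhancer pools, private cell-specific sets) are
    registered here so later placements can be forced to keep their
    distance (a >= 1 bp gap blocks both overlap and book-ended merging).
    """

    def __init__(self) -> None:
        self._by: dict[str, tuple[list[int], list[int]]] = {}

    def overlaps(self, chrom: str, start: int, end: int, margin: int = 1) -> bool:
        entry = self._by.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect_left(starts, end + margin)
        # candidate conflicts with interval i-1 (the last with start < end+margin)
        return i > 0 and ends[i - 1] + margin > start

    def add(self, chrom: str, start: int, end: int) -> None:
        starts, ends = self._by.setdefault(chrom, ([], []))
        i = bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


class _GeneIndex:
    """Flat arrays of TSSs with gaps to the neighbouring TSS on each side."""

    def __init__(self, tss: pd.DataFrame, chrom_sizes: dict[str, int]) -> None:
        self.chrom = tss["chrom"].to_numpy(dtype=object)
        self.pos = tss["pos"].to_numpy(dtype=np.int64)
        self.strand = tss["strand"].to_numpy(dtype=object)
        self.size = np.array([chrom_sizes[c] for c in self.chrom], dtype=np.int64)
        n = len(tss)
        self.left_gap = np.empty(n, dtype=np.int64)
        self.right_gap = np.empty(n, dtype=np.int64)
        for chrom, sub in tss.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            p = sub["pos"].to_numpy(np.int64)
            order = np.argsort(p, kind="mergesort")
            sidx, sp = idx[order], p[order]
            L = chrom_sizes[str(chrom)]
            lg = np.diff(np.concatenate([[0], sp]))
            rg = np.diff(np.concatenate([sp, [L]]))
            self.left_gap[sidx] = lg
            self.right_gap[sidx] = rg

    def __len__(self) -> int:
        return len(self.pos)


def _sample_width(rng: np.random.Generator, arch: FactorArchetype) -> int:
    w = math.exp(rng.normal(math.log(arch.width_median), arch.width_sigma_log))
    return max(50, int(round(w)))


def _try_place(
    rng: np.random.Generator,
    genes: _GeneIndex,
    category: str,
    width: int,
) -> tuple[str, int, int] | None:
    """One placement attempt for a peak of the given location category.

    Distal peaks are offset log-uniformly in [1 kb, 100 kb] from a random
    gene's TSS, clamped to half the gap to the neighbouring TSS so the
    planted gene is guaranteed to remain the nearest one (this is what
    makes archetype fractions exactly recoverable).
    """
    g = int(rng.integers(len(genes)))
    pos, strand, L = int(genes.pos[g]), genes.strand[g], int(genes.size[g])
    chrom = genes.chrom[g]
    if category == "tss":
        start = min(max(pos - width // 2, 0), L - width)
        if not (start <= pos < start + width):
            return None
        return chrom, start, start + width
    # physical side: upstream of '+' and downstream of '-' lie left of the TSS
    left = (category == "up") == (strand == "+")
    gap = int(genes.left_gap[g] if left else genes.right_gap[g])
    o_max = min(MAX_DISTAL_OFFSET, (gap - width) // 2 - 1)
    if o_max < MIN_DISTAL_OFFSET:
        return None
    o = int(round(math.exp(rng.uniform(math.log(MIN_DISTAL_OFFSET), math.log(o_max)))))
    if left:
        start = pos - o - width + 1
    else:
        start = pos + o
    if start < 0 or start + width > L:
        return None
    return chrom, start, start + width


def _place_peaks(
    rng: np.random.Generator,
    genes: _GeneIndex,
    arch: FactorArchetype,
    categories: list[str],
    avoid: list[_Registry],
    register: _Registry | None = None,
    max_tries: int = 500,
) -> list[tuple[str, int, int]]:
    """Place one peak per requested category, honouring rejection registries."""
    out = []
    for cat in categories:
        placed = None
        for _ in range(max_tries):
            width = _sample_width(rng, arch)
            cand = _try_place(rng, genes, cat, width)
            if cand is None:
                continue
            if any(reg.overlaps(*cand) for reg in avoid):
                continue
            placed = cand
            break
        if placed is None:
            raise RuntimeError(
                f"could not place a {cat!r} peak for {arch.name} after {max_tries} tries;"
                " genome too crowded for the requested region sets"
            )
        if register is not None:
            register.add(*placed)
        out.append(placed)
    return out


def _categories(rng: np.random.Generator, arch: FactorArchetype, n: int) -> list[str]:
    return list(rng.choice(["tss", "up", "down"], size=n, p=[arch.p_tss, arch.p_up, arch.p_down]))


def _peaks_frame(intervals: list[tuple[str, int, int]]) -> pd.DataFrame:
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Experiments


def simulate_experiments(
    truth: GroundTruth,
    tss: pd.DataFrame,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator | None = None,
    n_replicates: int = 1,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate the manifest and per-experiment peak tables for one species.

    Returns ``(manifest, peaks)`` where ``manifest`` has the standard
    columns (``peak_path`` left empty; filled when written to disk) and
    ``peaks`` maps experiment id to a sorted peaks DataFrame.
    """
    rng = rng or np.random.default_rng(truth.seed)
    genes = _GeneIndex(tss.reset_index(drop=True), chrom_sizes)
    reserved = _Registry()  # planted module regions; everyone keeps out
    structured = _Registry()  # anchors, pools, private sets; mutually disjoint

    by_name = {f.name: f for f in truth.factors}
    module_regions: dict[str, list[tuple[str, int, int]]] = {}
    member_of: dict[str, CoModule] = {}
    for mod in truth.modules:
        arch0 = by_name[mod.members[0]]
        cats = list(rng.choice(["up", "down"], size=mod.n_regions))
        regions = _place_peaks(
            rng, genes, arch0, cats, avoid=[reserved, structured], register=structured
        )
        for r in regions:
            reserved.add(*r)
        module_regions[mod.module_id] = regions
        for m in mod.members:
            member_of[m] = mod

    # per-cell-type shared enhancer pools for cell-specific factors
    pool_arch = FactorArchetype("pool", "distal_cell_specific", 0.0, 0.5, 0.5, n_peaks=1)
    pools: dict[str, list[tuple[str, int, int]]] = {}
    for ct in truth.cell_types:
        cats = list(rng.choice(["up", "down"], size=truth.enhancer_pool_size))
        pools[ct] = _place_peaks(
            rng, genes, pool_arch, cats, avoid=[reserved, structured], register=structured
        )

    # one fixed anchor set per distal_shared factor, reused across cell types
    shared_anchors: dict[str, list[tuple[str, int, int]]] = {}
    for arch in truth.factors:
        if arch.kind == "distal_shared":
            cats = _categories(rng, arch, arch.n_peaks)
            shared_anchors[arch.name] = _place_peaks(
                rng, genes, arch, cats, avoid=[reserved, structured], register=structured
            )

    manifest_rows = []
    peaks: dict[str, pd.DataFrame] = {}

    def _cell_specific_peaks(arch: FactorArchetype, ct: str) -> list[tuple[str, int, int]]:
        cats = _categories(rng, arch, arch.n_peaks)
        n_distal = sum(c != "tss" for c in cats)
        n_pool = int(round(arch.pool_share * n_distal))
        n_pool = min(n_pool, len(pools[ct]))
        idx = rng.choice(len(pools[ct]), size=n_pool, replace=False)
        out = [pools[ct][i] for i in idx]
        # remaining distal peaks are fresh, private placements
        fresh_cats = [c for c in cats if c != "tss"][n_pool:]
        out += _place_peaks(
            rng, genes, arch, fresh_cats, avoid=[reserved, structured], register=structured
        )
        out += _place_peaks(
            rng, genes, arch, [c for c in cats if c == "tss"], avoid=[reserved]
        )
        return out

    for ct in truth.cell_types:
        for arch in truth.factors:
            if arch.cell_types is not None and ct not in arch.cell_types:
                continue
            if arch.kind == "distal_shared":
                n_keep = int(round(truth.shared_resample * len(shared_anchors[arch.name])))
                idx = rng.choice(len(shared_anchors[arch.name]), size=n_keep, replace=False)
                base = [shared_anchors[arch.name][i] for i in idx]
            elif arch.kind == "distal_cell_specific":
                base = _cell_specific_peaks(arch, ct)
            else:  # promoter / downstream_biased / upstream_biased: fresh draws
                cats = _categories(rng, arch, arch.n_peaks)
                base = _place_peaks(rng, genes, arch, cats, avoid=[reserved])
            if arch.name in member_of and member_of[arch.name].cell_type == ct:
                base = base + module_regions[member_of[arch.name].module_id]
            for rep in range(1, n_replicates + 1):
                if rep == 1:
                    ivs = base
                    eid = f"{truth.species}_{ct}_{arch.name}"
                else:
                    n_keep = int(round(truth.replicate_resample * len(base)))
                    idx = rng.choice(len(base), size=n_keep, replace=False)
                    ivs = [base[i] for i in sorted(idx)]
                    eid = f"{truth.species}_{ct}_{arch.name}_r{rep}"
                manifest_rows.append(
                    {
                        "experiment_id": eid,
                        "factor": arch.name,
                        "cell_type": ct,
                        "species": truth.species,
                        "peak_path": "",
                    }
                )
                peaks[eid] = _peaks_frame(ivs)

    manifest = pd.DataFrame(manifest_rows)
    return manifest, peaks


# ---------------------------------------------------------------------------
# GWAS hits


def simulate_gwas(
    truth: GroundTruth,
    chrom_sizes: dict[str, int],
    peaks: dict[str, pd.DataFrame],
    manifest: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Place trait hits with the planted factor's regions enriched.

    With coverage fraction c of the planted factor's peak union and target
    per-bp rate ratio r, a hit is placed inside the union with probability
    q = c(r-1)/(1 + c(r-1)) and uniformly over the genome otherwise; the
    in-region/background rate ratio is then exactly r. r = 1 degenerates
    to a fully uniform catalog.
    """
    from .intervals import GenomicInterval, merge_intervals

    rng = rng or np.random.default_rng(truth.seed + 1)
    n_hits = truth.gwas_n_hits
    if n_hits == 0:
        return pd.DataFrame(columns=["chrom", "pos", "trait"])
    planted_ids = manifest.loc[manifest["factor"] == truth.gwas_factor, "experiment_id"]
    union = merge_intervals(
        [
            GenomicInterval(c, int(s), int(e))
            for eid in planted_ids
            for c, s, e in zip(peaks[eid]["chrom"], peaks[eid]["start"], peaks[eid]["end"])
        ]
    )
    total = sum(chrom_sizes.values())
    covered = sum(iv.end - iv.start for iv in union)
    c = covered / total
    r = truth.gwas_enrichment
    q = c * (r - 1) / (1 + c * (r - 1)) if r > 1 else 0.0
    widths = np.array([iv.end - iv.start for iv in union], dtype=np.float64)
    w = widths / widths.sum() if len(widths) else widths
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[cn] for cn in chroms], dtype=np.float64)
    rows = []
    for _ in range(n_hits):
        if len(union) and rng.random() < q:
            iv = union[int(rng.choice(len(union), p=w))]
            pos = int(rng.integers(iv.start, iv.end))
            chrom = iv.chrom
        else:
            ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
            chrom = chroms[ci]
            pos = int(rng.integers(0, chrom_sizes[chrom]))
        rows.append((chrom, pos, TRAIT_VOCABULARY[int(rng.integers(len(TRAIT_VOCABULARY)))]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "trait"])


# ---------------------------------------------------------------------------
# Default study design


def default_truth(species: str = "human", seed: int = 0, scale: float = 1.0) -> GroundTruth:
    """The default planted study design for one species.

    Human gets three cell types, mouse two. Factor names are cased
    per species (CTCF vs Ctcf) to exercise case-insensitive cross-species
    matching. ``scale`` multiplies peak counts, pool and module sizes and
    the GWAS catalog size (used to shrink test datasets).
    """
    if species == "human":
        cell_types = ["ESC", "GM12878", "K562"]
        case = str.upper
    elif species == "mouse":
        cell_types = ["mESC", "MEL"]
        case = str.capitalize
    else:
        raise ValueError(f"unknown species {species!r}")
    s = lambda n: max(1, int(round(n * scale)))
    mod_cell = cell_types[0]
    factors = [
        FactorArchetype(case("polr2a"), "promoter", 0.80, 0.10, 0.10, n_peaks=s(1200)),
        FactorArchetype(case("brca1"), "promoter", 0.70, 0.15, 0.15, n_peaks=s(1000)),
        FactorArchetype(case("ctcf"), "distal_shared", 0.15, 0.45, 0.40, n_peaks=s(1500)),
        FactorArchetype(
            case("ep300"), "distal_cell_specific", 0.10, 0.45, 0.45,
            n_peaks=s(1000), pool_share=0.8,
        ),
        FactorArchetype(
            case("jun"), "distal_cell_specific", 0.10, 0.45, 0.45,
            n_peaks=s(1000), pool_share=0.8,
        ),
        FactorArchetype(
            case("nelfe"), "distal_cell_specific", 0.10, 0.45, 0.45, n_peaks=s(1000),
        ),
        FactorArchetype(case("znf274"), "downstream_biased", 0.15, 0.25, 0.60, n_peaks=s(800)),
        FactorArchetype(case("polr3g"), "upstream_biased", 0.20, 0.60, 0.20, n_peaks=s(800)),
        FactorArchetype(
            case("oct4"), "distal_cell_specific", 0.10, 0.45, 0.45,
            n_peaks=s(700), co_module="OSN", cell_types=[mod_cell],
        ),
        FactorArchetype(
            case("sox2"), "distal_cell_specific", 0.10, 0.45, 0.45,
            n_peaks=s(700), co_module="OSN", cell_types=[mod_cell],
        ),
        FactorArchetype(
            case("nanog"), "distal_cell_specific", 0.10, 0.45, 0.45,
            n_peaks=s(700), co_module="OSN", cell_types=[mod_cell],
        ),
    ]
    modules = [
        CoModule(
            "OSN",
            [case("oct4"), case("sox2"), case("nanog")],
            cell_type=mod_cell,
            n_regions=s(1000),
        )
    ]
    return GroundTruth(
        species=species,
        cell_types=cell_types,
        factors=factors,
        modules=modules,
        gwas_factor=case("nelfe"),
        gwas_enrichment=3.0,
        gwas_n_hits=s(2000),
        enhancer_pool_size=s(1500),
        seed=seed,
    )


@dataclass
class SyntheticDataset:
    """One species' generated dataset, fully in memory."""

    truth: GroundTruth
    tss: pd.DataFrame
    chrom_sizes: dict[str, int]
    manifest: pd.DataFrame
    peaks: dict[str, pd.DataFrame]
    gwas: pd.DataFrame


def simulate_in_memory(
    seed: int = 0,
    species: tuple[str, ...] = ("human", "mouse"),
    scale: float = 1.0,
    n_replicates: int = 1,
) -> dict[str, SyntheticDataset]:
    """Generate complete datasets for the requested species, in memory."""
    out: dict[str, SyntheticDataset] = {}
    for i, sp in enumerate(species):
        sp_seed = (seed + 7919 * i) % (2**31)
        truth = default_truth(sp, seed=sp_seed, scale=scale)
        tss, sizes = simulate_genome(GenomeSpec(seed=sp_seed))
        rng = np.random.default_rng(sp_seed + 1)
        manifest, peaks = simulate_experiments(
            truth, tss, sizes, rng=rng, n_replicates=n_replicates
        )
        gwas = simulate_gwas(truth, sizes, peaks, manifest, rng=rng)
        out[sp] = SyntheticDataset(truth, tss, sizes, manifest, peaks, gwas)
    return out


def simulate_dataset(
    outdir: str | Path,
    seed: int = 0,
    species: tuple[str, ...] = ("human", "mouse"),
    scale: float = 1.0,
    n_replicates: int = 1,
) -> dict[str, Path]:
    """Generate datasets and write every artifact to ``outdir``.

    Emits one manifest covering all species, one BED per experiment under
    ``peaks/``, per-species TSS BEDs, GWAS catalogs, chromosome-size
    tables, and the ground truth as JSON. Returns the artifact paths.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    datasets = simulate_in_memory(seed, species, scale, n_replicates)
    manifests = []
    truth_blob: dict[str, dict] = {"seed": seed, "scale": scale, "species": {}}
    paths: dict[str, Path] = {}
    for sp, ds in datasets.items():
        for eid, pk in ds.peaks.items():
            rel = Path("peaks") / f"{eid}.bed"
            psio.write_bed(pk, outdir / rel)
            ds.manifest.loc[ds.manifest["experiment_id"] == eid, "peak_path"] = str(rel)
        manifests.append(ds.manifest)
        psio.write_tss_bed(ds.tss, outdir / f"tss_{sp}.bed")
        psio.write_gwas_catalog(ds.gwas, outdir / f"gwas_{sp}.tsv")
        pd.DataFrame(
            {"chrom": list(ds.chrom_sizes), "size": list(ds.chrom_sizes.values())}
        ).to_csv(outdir / f"genome_{sp}.tsv", sep="\t", index=False)
        truth_blob["species"][sp] = ds.truth.to_json()
        paths[f"tss_{sp}"] = outdir / f"tss_{sp}.bed"
        paths[f"gwas_{sp}"] = outdir / f"gwas_{sp}.tsv"
        paths[f"genome_{sp}"] = outdir / f"genome_{sp}.tsv"
    manifest = pd.concat(manifests, ignore_index=True)
    psio.write_manifest(manifest, outdir / "manifest.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_blob, fh, indent=1, sort_keys=True)
    paths["manifest"] = outdir / "manifest.tsv"
    paths["truth"] = outdir / "truth.json"
    return paths
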