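"""Stage orchestration: run the whole analysis from a flat config file.

Stages (in dependency order): ``simulate`` (optional, generates a
synthetic dataset), ``matrix``, ``heatmap``, ``tss``, ``hotspots``,
``combos``, ``gwas``; ``all`` runs everything after ``simulate`` in
topological order. Each stage reads only on-disk artifacts, writes its
outputs under the output directory, appends to a machine-readable
``summary.json`` and echoes the fully-resolved config, so re-running a
deterministic stage with identical config and inputs is byte-identical.

All randomness flows from the single config seed through per-stage seeds
derived by hashing the stage name, so stages are independently
reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import combinations as combi
from . import cooccurrence as cooc
from . import gwas as gwasmod
from . import hotspots as hot
from . import io as psio
from . import simulate as sim
from . import tss_preference as tssp
from .intervals import GenomicInterval, merge_intervals, nearest_tss, annotations_to_frame

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_stage", "STAGES"]

STAGES = ["simulate", "matrix", "heatmap", "tss", "hotspots", "combos", "gwas"]
_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    outdir: str = "peakscape_out"
    manifest: str = ""  # defaults to <outdir>/simulate/manifest.tsv
    tss_tables: dict[str, str] = field(default_factory=dict)  # species -> path
    gwas_tables: dict[str, str] = field(default_factory=dict)
    proximal_bp: int = 1000
    distal_bp: int = 10000
    min_experiments_per_cell_type: int = 30
    min_factors_combinatorial: int = 6
    n_rand: int = 100
    kmeans_k: int = 6
    alpha: float = 0.05
    gwas_window: int = 0
    simulate_scale: float = 1.0
    simulate_species: str = "human,mouse"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("proximal_bp", "distal_bp", "min_experiments_per_cell_type",
                     "min_factors_combinatorial", "n_rand", "kmeans_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"config: {name} must be non-negative")
        if not (0 < self.alpha < 1):
            raise ValueError("config: alpha must be in (0, 1)")
        if self.proximal_bp > self.distal_bp:
            raise ValueError("config: proximal_bp must not exceed distal_bp")

    # -- flat key=value file format ------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kv: dict[str, str] = {}
        for lineno, line in enumerate(open(path), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
        return cls.from_mapping(kv)

    @classmethod
    def from_mapping(cls, kv: dict[str, str]) -> "PipelineConfig":
        kwargs: dict = {}
        tss, gw = {}, {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for k, v in kv.items():
            if k.startswith("tss_"):
                tss[k[4:]] = v
            elif k.startswith("gwas_"):
                gw[k[5:]] = v
            elif k in fields:
                typ = {"int": int, "float": float, "str": str}.get(fields[k], str)
                kwargs[k] = typ(v)
            else:
                raise ValueError(f"unknown config key {k!r}")
        return cls(tss_tables=tss, gwas_tables=gw, **kwargs)

    def to_text(self) -> str:
        d = asdict(self)
        tss = d.pop("tss_tables")
        gw = d.pop("gwas_tables")
        lines = [f"{k}={v}" for k, v in sorted(d.items())]
        lines += [f"tss_{sp}={p}" for sp, p in sorted(tss.items())]
        lines += [f"gwas_{sp}={p}" for sp, p in sorted(gw.items())]
        return "\n".join(lines) + "\n"

    def stage_seed(self, stage: str) -> int:
        return (self.seed + zlib.crc32(stage.encode())) % (2**31)

    # -- resolved input locations --------------------------------------
    def manifest_path(self) -> Path:
        return Path(self.manifest) if self.manifest else Path(self.outdir) / "simulate" / "manifest.tsv"

    def tss_path(self, species: str) -> Path:
        if species in self.tss_tables:
            return Path(self.tss_tables[species])
        return Path(self.outdir) / "simulate" / f"tss_{species}.bed"

    def gwas_path(self, species: str) -> Path | None:
        if species in self.gwas_tables:
            return Path(self.gwas_tables[species])
        p = Path(self.outdir) / "simulate" / f"gwas_{species}.tsv"
        return p if p.exists() else None


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the {producer!r} stage first"
        )
    return path


def _update_summary(outdir: Path, stage: str, payload: dict) -> None:
    path = outdir / "summary.json"
    blob = json.loads(path.read_text()) if path.exists() else {}
    blob[stage] = payload
    path.write_text(json.dumps(blob, indent=1, sort_keys=True) + "\n")


def _echo_config(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.txt").write_text(cfg.to_text())


def _load_manifest(cfg: PipelineConfig) -> pd.DataFrame:
    return psio.read_manifest(_require(cfg.manifest_path(), "simulate"))


def _load_peaks(manifest: pd.DataFrame) -> dict[str, list[GenomicInterval]]:
    return {
        row.experiment_id: psio.peaks_to_intervals(psio.read_peaks_bed(row.peak_path))
        for row in manifest.itertuples()
    }


def _matrix_dir(cfg: PipelineConfig, species: str) -> Path:
    return Path(cfg.outdir) / "matrix" / species


def _write_matrix(bm: cooc.BindingMatrix, d: Path) -> None:
    d.mkdir(parents=True, exist_ok=True)
    psio.write_bed(bm.regions_frame(), d / "regions.bed")
    scipy.io.mmwrite(str(d / "occupancy.mtx"), scipy.sparse.csc_matrix(bm.occupancy))
    cols = bm.meta.drop(columns=["peak_path"], errors="ignore")
    cols = cols.assign(is_reference=bm.is_reference.astype(int))
    cols.to_csv(d / "columns.tsv", sep="\t", index=False)


def _read_matrix(d: Path) -> cooc.BindingMatrix:
    regions = [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in psio.read_peaks_bed(d / "regions.bed")[["chrom", "start", "end"]].itertuples(index=False)
    ]
    occ = np.asarray(scipy.io.mmread(str(d / "occupancy.mtx")).todense(), dtype=np.uint8)
    cols = pd.read_csv(d / "columns.tsv", sep="\t", dtype=str)
    is_ref = cols.pop("is_reference").astype(int).to_numpy(dtype=bool)
    return cooc.BindingMatrix(
        regions=regions,
        experiments=list(cols["experiment_id"]),
        occupancy=occ,
        is_reference=is_ref,
        meta=cols,
    )


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir) / "simulate"
    species = tuple(s for s in cfg.simulate_species.split(",") if s)
    sim.simulate_dataset(out, seed=cfg.stage_seed("simulate"), species=species,
                         scale=cfg.simulate_scale)
    manifest = psio.read_manifest(out / "manifest.tsv")
    return {
        "n_experiments": int(len(manifest)),
        "species": sorted(manifest["species"].unique()),
    }


def stage_matrix(cfg: PipelineConfig) -> dict:
    manifest = _load_manifest(cfg)
    peaks = _load_peaks(manifest)
    info = {}
    for sp, sub in manifest.groupby("species"):
        bm = cooc.build_matrix(sub.reset_index(drop=True), peaks)
        tss_p = cfg.tss_path(str(sp))
        if tss_p.exists():
            tss = psio.read_tss_bed(tss_p)
            pts = [GenomicInterval(c, int(p), int(p) + 1) for c, p in zip(tss["chrom"], tss["pos"])]
            bm = cooc.add_reference_track(bm, pts, "TSS")
        _write_matrix(bm, _matrix_dir(cfg, str(sp)))
        info[str(sp)] = {"M_regions": bm.n_regions, "N_experiments": int((~bm.is_reference).sum())}
    return info


def stage_heatmap(cfg: PipelineConfig, plot: bool = True) -> dict:
    manifest = _load_manifest(cfg)
    info = {}
    for sp in sorted(manifest["species"].unique()):
        d = _matrix_dir(cfg, sp)
        _require(d / "occupancy.mtx", "matrix")
        bm = _read_matrix(d)
        cl = cooc.cluster_matrix(bm)
        out = Path(cfg.outdir) / "heatmap"
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(cl.corr, index=cl.labels, columns=cl.labels).to_csv(
            out / f"corr_{sp}.tsv", sep="\t", float_format=_FLOAT_FMT
        )
        pd.DataFrame({"order": cl.leaf_order, "experiment_id": cl.ordered_labels()}).to_csv(
            out / f"leaf_order_{sp}.tsv", sep="\t", index=False
        )
        if plot:
            _plot_heatmap(cl, bm, out / f"heatmap_{sp}.png")
        info[sp] = {"mean_offdiag_corr": float(
            (cl.corr.sum() - len(cl.labels)) / (len(cl.labels) ** 2 - len(cl.labels))
        )}
    return info


def _plot_heatmap(cl: cooc.CorrelationClustering, bm: cooc.BindingMatrix, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = cl.leaf_order
    C = cl.corr[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(C, cmap="RdBu_r", vmin=-1, vmax=1)
    labels = cl.ordered_labels()
    ax.set_xticks(range(len(labels)))
    ax.set_yticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=5)
    ax.set_yticklabels(labels, fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson correlation (phi)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stage_tss(cfg: PipelineConfig) -> dict:
    manifest = _load_manifest(cfg)
    out = Path(cfg.outdir) / "tss"
    out.mkdir(parents=True, exist_ok=True)
    info = {}
    profiles_by_species: dict[str, pd.DataFrame] = {}
    for sp, sub in manifest.groupby("species"):
        sp = str(sp)
        tss = psio.read_tss_bed(_require(cfg.tss_path(sp), "simulate"))
        profs = []
        for row in sub.itertuples():
            pk = psio.read_peaks_bed(row.peak_path)
            ann = nearest_tss(psio.peaks_to_intervals(pk), tss)
            d = np.array([a.distance for a in ann])
            p = tssp.location_profile(d, row.experiment_id)
            profs.append(vars(p) | {"factor": row.factor, "cell_type": row.cell_type})
        pf = pd.DataFrame(profs)[
            ["experiment_id", "factor", "cell_type", "n_peaks", "f_up", "f_tss", "f_down", "group"]
        ]
        pf.to_csv(out / f"profiles_{sp}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        profiles_by_species[sp] = pf
        # per-region distances for the species matrix (consumed by hotspots)
        d_mat = _matrix_dir(cfg, sp)
        if (d_mat / "regions.bed").exists():
            bm_regions = psio.read_peaks_bed(d_mat / "regions.bed")
            ann = nearest_tss(
                [GenomicInterval(c, int(s), int(e)) for c, s, e in
                 bm_regions[["chrom", "start", "end"]].itertuples(index=False)],
                tss,
            )
            annotations_to_frame(ann).to_csv(
                out / f"region_distances_{sp}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )
        info[sp] = {
            "n_experiments": int(len(pf)),
            "groups": pf["group"].value_counts().to_dict(),
        }
    if len(profiles_by_species) >= 2:
        sps = sorted(profiles_by_species)
        comp = tssp.compare_species(profiles_by_species[sps[0]], profiles_by_species[sps[1]])
        comp.per_factor.to_csv(
            out / f"species_comparison_{sps[0]}_vs_{sps[1]}.tsv",
            sep="\t", index=False, float_format=_FLOAT_FMT,
        )
        info["comparison"] = {
            "species": sps,
            "pearson_r": comp.pearson_r,
            "slope": comp.slope,
            "intercept": comp.intercept,
        }
    return info


def stage_hotspots(cfg: PipelineConfig) -> dict:
    manifest = _load_manifest(cfg)
    out = Path(cfg.outdir) / "hotspots"
    out.mkdir(parents=True, exist_ok=True)
    info = {}
    for sp, sub in manifest.groupby("species"):
        sp = str(sp)
        d_mat = _matrix_dir(cfg, sp)
        _require(d_mat / "occupancy.mtx", "matrix")
        dist_path = _require(Path(cfg.outdir) / "tss" / f"region_distances_{sp}.tsv", "tss")
        bm = _read_matrix(d_mat)
        dists = pd.read_csv(dist_path, sep="\t")["distance"].to_numpy()
        prox, dist = hot.split_by_proximity(bm, dists, cfg.proximal_bp, cfg.distal_bp)
        sp_info: dict = {
            "n_regions": bm.n_regions,
            "n_proximal": prox.n_regions,
            "n_distal": dist.n_regions,
        }
        for name, sub_bm in (("proximal", prox), ("distal", dist)):
            if sub_bm.n_regions >= 2:
                cl = cooc.cluster_matrix(sub_bm)
                pd.DataFrame(cl.corr, index=cl.labels, columns=cl.labels).to_csv(
                    out / f"corr_{name}_{sp}.tsv", sep="\t", float_format=_FLOAT_FMT
                )
                n = len(cl.labels)
                sp_info[f"mean_corr_{name}"] = float(
                    (cl.corr.sum() - n) / (n**2 - n)
                )
        cell_types = hot.select_cell_types(sub, cfg.min_experiments_per_cell_type)
        if cell_types:
            sel = bm  # density over all regions; columns restricted per cell type below
            dm = hot.tf_density(sel, cell_types)
            k = min(cfg.kmeans_k, dm.density.shape[0])
            hc = hot.cluster_hotspots(dm, k=k, seed=cfg.stage_seed("hotspots"), distances=dists)
            summary = hc.summary()
            if hc.proximity_composition is not None:
                summary = summary.merge(hc.proximity_composition, on="cluster")
            summary.to_csv(out / f"clusters_{sp}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            reg = bm.regions_frame()
            reg["name"] = [f"cluster{c}" for c in hc.assignment]
            psio.write_bed(reg, out / f"cluster_assignments_{sp}.bed")
            sp_info["cell_types"] = cell_types
            sp_info["k"] = k
        else:
            sp_info["cell_types"] = []
        info[sp] = sp_info
    return info


def stage_combos(cfg: PipelineConfig) -> dict:
    manifest = _load_manifest(cfg)
    peaks = _load_peaks(manifest)
    out = Path(cfg.outdir) / "combos"
    out.mkdir(parents=True, exist_ok=True)
    all_results = []
    info = {}
    rng = np.random.default_rng(cfg.stage_seed("combos"))
    for sp, sub in manifest.groupby("species"):
        sp = str(sp)
        cts = combi.select_combinatorial_cell_types(sub, cfg.min_factors_combinatorial)
        info[sp] = {"cell_types": cts}
        for ct in cts:
            csub = sub[sub["cell_type"] == ct]
            factors = sorted(csub["factor"].unique())
            # collapse replicates: union of peaks per factor
            fac_peaks = {
                f: [iv for eid in csub.loc[csub["factor"] == f, "experiment_id"]
                    for iv in peaks[eid]]
                for f in factors
            }
            fac_manifest = pd.DataFrame(
                {
                    "experiment_id": factors,
                    "factor": factors,
                    "cell_type": ct,
                    "species": sp,
                    "peak_path": "",
                }
            )
            bm = cooc.build_matrix(fac_manifest, fac_peaks)
            res = combi.cell_type_enrichment(
                bm.occupancy, factors, n_rand=cfg.n_rand, seed=rng
            )
            res.insert(0, "cell_type", ct)
            res.insert(0, "species", sp)
            all_results.append(res)
    if all_results:
        combined = pd.concat(all_results, ignore_index=True)
    else:
        combined = pd.DataFrame()
    combined.to_csv(out / "combos.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    if len(combined):
        info["n_significant"] = int((combined["p_bonf"] < cfg.alpha).sum())
        top = combined.sort_values(["p_bonf", "observed"], ascending=[True, False]).iloc[0]
        info["top_pattern"] = {
            "cell_type": str(top["cell_type"]),
            "pattern": str(top["pattern_name"]),
            "observed": int(top["observed"]),
            "p_bonf": float(top["p_bonf"]),
        }
    return info


def stage_gwas(cfg: PipelineConfig) -> dict:
    manifest = _load_manifest(cfg)
    out = Path(cfg.outdir) / "gwas"
    out.mkdir(parents=True, exist_ok=True)
    info = {}
    frames = []
    breakdowns = []
    for sp in sorted(manifest["species"].unique()):
        gp = cfg.gwas_path(sp)
        if gp is None or not Path(gp).exists():
            logger.info("no GWAS catalog for species %s; skipped", sp)
            continue
        d_mat = _matrix_dir(cfg, sp)
        _require(d_mat / "occupancy.mtx", "matrix")
        bm = _read_matrix(d_mat)
        hits = psio.read_gwas_catalog(gp)
        marked, traits = gwasmod.mark_gwas_regions(bm.regions, hits, cfg.gwas_window)
        results = gwasmod.test_all_experiments(bm, marked, traits, alpha=cfg.alpha)
        df = gwasmod.results_frame(results, bm.meta)
        df.insert(0, "species", sp)
        frames.append(df)
        for r in results:
            if r.significant:
                for trait, cnt in sorted(r.trait_counts.items()):
                    breakdowns.append(
                        {"species": sp, "experiment_id": r.experiment_id,
                         "trait": trait, "n_regions": cnt}
                    )
        info[sp] = {
            "n_tested": len(results),
            "n_significant": int(sum(r.significant for r in results)),
            "significant": [r.experiment_id for r in results if r.significant],
        }
    pd.concat(frames, ignore_index=True).to_csv(
        out / "gwas_results.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    ) if frames else pd.DataFrame().to_csv(out / "gwas_results.tsv", sep="\t", index=False)
    pd.DataFrame(breakdowns, columns=["species", "experiment_id", "trait", "n_regions"]).to_csv(
        out / "trait_breakdown.tsv", sep="\t", index=False
    )
    return info


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "matrix": stage_matrix,
    "heatmap": stage_heatmap,
    "tss": stage_tss,
    "hotspots": stage_hotspots,
    "combos": stage_combos,
    "gwas": stage_gwas,
}


def run_stage(stage: str, cfg: PipelineConfig) -> dict:
    """Run one stage (or ``all``: everything after ``simulate``).

    Validates the config, echoes it next to the outputs, and records each
    stage's key counts in ``summary.json``. Missing upstream artifacts
    raise a :class:`FileNotFoundError` naming the stage to run first.
    """
    _echo_config(cfg)
    outdir = Path(cfg.outdir)
    if stage == "all":
        info = {}
        for s in ["matrix", "heatmap", "tss", "hotspots", "combos", "gwas"]:
            logger.info("running stage %s", s)
            info[s] = _STAGE_FUNCS[s](cfg)
            _update_summary(outdir, s, info[s])
        return info
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ['all']}")
    payload = _STAGE_FUNCS[stage](cfg)
    _update_summary(outdir, stage, payload)
    return payload
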