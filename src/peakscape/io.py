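"""Readers and writers for every on-disk artifact the pipeline touches.

Dialects are strict and documented:

* **Peaks** — BED3+ (tab-separated, optional ``track``/``browser``/``#``
  header lines). Coordinates are 0-based half-open; zero-length intervals
  (``start == end``) are rejected. Columns beyond the third are preserved
  as opaque string annotations.
* **TSS table** — 6-column BED, one point interval per gene
  (``chrom, pos, pos+1, gene_id, 0, strand``).
* **Experiment manifest** — TSV with header
  ``experiment_id, factor, cell_type, species, peak_path``.
* **GWAS catalog** — TSV with header containing at least
  ``CHR_ID, CHR_POS, DISEASE/TRAIT``; positions are 1-based in the file and
  converted to 0-based on read.

Everything inside the package is 0-based half-open; every reader converts
on entry and every writer on exit.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "read_peaks_bed",
    "write_bed",
    "read_tss_bed",
    "write_tss_bed",
    "derive_tss_table",
    "read_manifest",
    "write_manifest",
    "read_gwas_catalog",
    "write_gwas_catalog",
    "normalize_chrom",
    "peaks_to_intervals",
]

#: fixed alias table for chromosome-name normalization
_CHROM_ALIASES = {"MT": "chrM", "M": "chrM", "Mito": "chrM"}

_HEADER_RE = re.compile(r"^(track|browser|#)")


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name: ``"1"`` → ``"chr1"``, ``"MT"`` → ``"chrM"``.

    Names already starting with ``chr`` are returned unchanged (case of the
    rest preserved).
    """
    name = name.strip()
    if name.startswith("chr"):
        return name
    if name in _CHROM_ALIASES:
        return _CHROM_ALIASES[name]
    return "chr" + name


class BedParseError(ValueError):
    """Raised on a malformed BED line; the message names the line number."""


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ peak file into a sorted DataFrame.

    Returns columns ``chrom, start, end`` plus ``extra1..extraK`` for any
    additional BED columns, sorted by ``(chrom, start, end)``. An empty file
    yields an empty frame (not an error).
    """
    rows: list[list] = []
    n_extra = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or _HEADER_RE.match(line):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from None
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}) "
                    "(need 0 <= start < end; zero-length peaks are rejected)"
                )
            extras = fields[3:]
            n_extra = max(n_extra, len(extras))
            rows.append([normalize_chrom(fields[0]), start, end, *extras])
    cols = ["chrom", "start", "end"] + [f"extra{i + 1}" for i in range(n_extra)]
    for r in rows:
        r.extend([""] * (len(cols) - len(r)))
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    df["start"] = df.get("start", pd.Series(dtype=np.int64)).astype(np.int64)
    df["end"] = df.get("end", pd.Series(dtype=np.int64)).astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write a peaks DataFrame back to BED; round-trips coordinates exactly."""
    cols = [c for c in df.columns]
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write("\t".join(str(getattr(row, c)) for c in cols) + "\n")


def peaks_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    """Convert a peaks DataFrame to a list of :class:`GenomicInterval`."""
    return [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]


# ---------------------------------------------------------------------------
# TSS tables


def derive_tss_table(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-transcript start sites to one median TSS per gene.

    ``transcripts`` needs columns ``gene_id, chrom, strand`` and either a
    ``pos`` column (per-transcript TSS points) or ``start``/``end``
    half-open coordinates, in which case the TSS of a ``+`` transcript is
    ``start`` and of a ``-`` transcript its last covered base ``end - 1``.

    The per-gene TSS is the median of its transcript TSS positions; for an
    even count the *lower* of the two middle values is taken so the result
    stays on an observed transcript start. A gene with transcripts on both
    strands is an error.
    """
    t = transcripts.copy()
    if "pos" not in t.columns:
        if not {"start", "end"} <= set(t.columns):
            raise ValueError("need either a 'pos' column or 'start'/'end' columns")
        t["pos"] = np.where(t["strand"] == "+", t["start"], t["end"] - 1)
    bad = t.groupby("gene_id")["strand"].nunique()
    bad = bad[bad > 1]
    if len(bad):
        raise ValueError(f"genes with transcripts on both strands: {sorted(bad.index)}")

    def _low_median(s: pd.Series) -> int:
        v = np.sort(s.to_numpy())
        return int(v[(len(v) - 1) // 2])

    agg = t.groupby("gene_id", sort=True).agg(
        chrom=("chrom", "first"), pos=("pos", _low_median), strand=("strand", "first")
    )
    out = agg.reset_index()[["gene_id", "chrom", "pos", "strand"]]
    if (out["pos"] < 0).any():
        raise ValueError("negative TSS position after derivation")
    return out


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read a 6-column BED of TSS points into ``gene_id, chrom, pos, strand``."""
    df = read_peaks_bed(path)
    if "extra3" not in df.columns:
        raise ValueError(f"{path}: TSS BED needs 6 columns (name, score, strand)")
    out = pd.DataFrame(
        {
            "gene_id": df["extra1"],
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64),
            "strand": df["extra3"],
        }
    )
    if not out["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: strand column must be '+' or '-'")
    if out["gene_id"].duplicated().any():
        dups = sorted(out.loc[out["gene_id"].duplicated(), "gene_id"].unique())
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    return out


def write_tss_bed(tss: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in tss.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.gene_id}\t0\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# Experiment manifest

_MANIFEST_COLS = ["experiment_id", "factor", "cell_type", "species", "peak_path"]


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Read and validate the experiment manifest TSV.

    Relative ``peak_path`` entries are resolved against the manifest's own
    directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    if df["experiment_id"].duplicated().any():
        dups = sorted(df.loc[df["experiment_id"].duplicated(), "experiment_id"])
        raise ValueError(f"{path}: duplicate experiment ids {dups}")
    for col in ("factor", "cell_type"):
        if df[col].isna().any() or (df[col].str.strip() == "").any():
            raise ValueError(f"{path}: empty values in column {col!r}")
    base = Path(path).parent
    df["peak_path"] = [
        str(p if Path(p).is_absolute() else base / p) for p in df["peak_path"]
    ]
    if check_paths:
        absent = [p for p in df["peak_path"] if not Path(p).exists()]
        if absent:
            raise FileNotFoundError(f"{path}: peak files not found: {absent}")
    return df[_MANIFEST_COLS].reset_index(drop=True)


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df[_MANIFEST_COLS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GWAS catalog

_GWAS_REQUIRED = ["CHR_ID", "CHR_POS", "DISEASE/TRAIT"]


def read_gwas_catalog(path: str | Path) -> pd.DataFrame:
    """Read a GWAS-catalog-style TSV into ``chrom, pos, trait`` (0-based).

    Rows with a missing or non-numeric position, or a multi-mapping
    chromosome field (``;`` or ``x`` separated), are dropped; the drop count
    is logged. Missing required columns raise a schema error naming them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _GWAS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: GWAS table missing required columns {missing}")
    total = len(df)
    multi = df["CHR_ID"].str.contains(r"[;x]", na=True) | (df["CHR_ID"].str.strip() == "")
    pos = pd.to_numeric(df["CHR_POS"], errors="coerce")
    keep = ~multi & pos.notna() & (pos >= 1)
    dropped = int(total - keep.sum())
    if dropped:
        logger.info("read_gwas_catalog: dropped %d of %d rows (%s)", dropped, total, path)
    out = pd.DataFrame(
        {
            "chrom": df.loc[keep, "CHR_ID"].map(normalize_chrom),
            "pos": (pos[keep] - 1).astype(np.int64),  # 1-based -> 0-based
            "trait": df.loc[keep, "DISEASE/TRAIT"],
        }
    ).reset_index(drop=True)
    out.attrs["n_dropped"] = dropped
    return out


def write_gwas_catalog(hits: pd.DataFrame, path: str | Path) -> None:
    """Write ``chrom, pos, trait`` hits in the catalog dialect (1-based)."""
    out = pd.DataFrame(
        {
            "CHR_ID": [c[3:] if c.startswith("chr") else c for c in hits["chrom"]],
            "CHR_POS": hits["pos"].astype(np.int64) + 1,
            "DISEASE/TRAIT": hits["trait"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
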