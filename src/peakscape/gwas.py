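"""Hypergeometric enrichment of ChIP-seq peak sets for GWAS trait loci.

The universe is the dataset's merged-region set (U regions bound by >= 1
experiment). K of them contain at least one GWAS hit. An experiment
binding n regions, k of which contain a hit, is scored by the upper-tail
hypergeometric probability P(X >= k) with X ~ Hypergeometric(U, K, n),
Bonferroni-corrected by the number of experiments tested. A region with
several hits counts once for the test but keeps its full trait set for
the per-trait breakdown of significant experiments (the "37 peaks overlap
inflammatory-bowel-disease loci" style of reporting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cooccurrence import BindingMatrix

__all__ = [
    "mark_gwas_regions",
    "hypergeometric_overlap",
    "hypergeometric_log_tails",
    "test_all_experiments",
]


def mark_gwas_regions(
    regions: list, hits: pd.DataFrame, window: int = 0
) -> tuple[np.ndarray, list[set]]:
    """Mark merged regions containing a GWAS hit (hit position +/- window).

    ``regions`` are sorted, disjoint intervals; ``hits`` has columns
    ``chrom, pos, trait`` with 0-based point positions. Returns the boolean
    marked vector and, per region, the set of traits whose hits fall in it.
    A hit at a region's exclusive end does not mark it (half-open).
    """
    marked = np.zeros(len(regions), dtype=bool)
    traits: list[set] = [set() for _ in regions]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    reg = pd.DataFrame(regions, columns=["chrom", "start", "end"])
    reg["idx"] = np.arange(len(reg))
    for chrom, sub in reg.groupby("chrom", sort=False):
        by_chrom[str(chrom)] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["idx"].to_numpy(np.int64),
        )
    for chrom, pos, trait in zip(hits["chrom"], hits["pos"], hits["trait"]):
        entry = by_chrom.get(str(chrom))
        if entry is None:
            continue
        starts, ends, idx = entry
        lo, hi = int(pos) - window, int(pos) + window  # inclusive point range
        i = int(np.searchsorted(ends, lo, side="right"))
        while i < len(starts) and starts[i] <= hi:
            marked[idx[i]] = True
            traits[idx[i]].add(trait)
            i += 1
    return marked, traits


def hypergeometric_log_tails(U: int, K: int, n: int) -> np.ndarray:
    """Log upper-tail probabilities log P(X >= k) for every k = 0..min(K, n).

    X ~ Hypergeometric(U, K, n). The pmf is assembled from log-gamma terms
    and the tails accumulated with ``logaddexp`` from the top down, so even
    astronomically small tails stay finite and accurate.
    """
    if not (0 <= K <= U and 0 <= n <= U):
        raise ValueError(f"invalid margins U={U}, K={K}, n={n}")
    lo = max(0, n - (U - K))  # smallest attainable count
    i = np.arange(lo, min(K, n) + 1)
    # log C(K, i) + log C(U-K, n-i) - log C(U, n)
    logpmf = (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(U - K + 1) - gammaln(n - i + 1) - gammaln(U - K - (n - i) + 1)
        - (gammaln(U + 1) - gammaln(n + 1) - gammaln(U - n + 1))
    )
    tails = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    if lo > 0:  # counts below the attainable range have tail probability 1
        tails = np.concatenate([np.zeros(lo), tails])
    tails[0] = 0.0  # P(X >= 0) = 1 exactly
    return np.minimum(tails, 0.0)


def hypergeometric_overlap(U: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), X ~ HG(U, K, n).

    Computed in log space for stability. Symmetric in (K, n).
    """
    if not (0 <= k <= min(K, n)):
        if 0 <= K <= U and 0 <= n <= U and k > min(K, n):
            raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
        raise ValueError(f"invalid parameters U={U}, K={K}, n={n}, k={k}")
    return float(np.exp(hypergeometric_log_tails(U, K, n)[k]))


@dataclass
class GWASResult:
    experiment_id: str
    U: int
    K: int
    n: int
    k: int
    fraction: float
    p_raw: float
    p_bonf: float
    significant: bool
    trait_counts: dict[str, int]


def test_all_experiments(
    matrix: BindingMatrix,
    marked: np.ndarray,
    traits: list[set] | None = None,
    alpha: float = 0.05,
) -> list[GWASResult]:
    """Hypergeometric GWAS-overlap test for every non-reference experiment.

    The Bonferroni family is the number of experiments tested. Results are
    sorted by (p_bonf, experiment_id). ``fraction`` is k/n (share of the
    experiment's bound regions that contain a hit, the "about 2% of the
    peaks" quantity); 0 when the experiment binds nothing.
    """
    marked = np.asarray(marked, dtype=bool)
    if len(marked) != matrix.n_regions:
        raise ValueError("marks and matrix disagree on the region universe")
    U = matrix.n_regions
    K = int(marked.sum())
    exp_cols = [
        (e, j)
        for j, e in enumerate(matrix.experiments)
        if not matrix.is_reference[j]
    ]
    family = len(exp_cols)
    results = []
    for eid, j in exp_cols:
        bound = matrix.occupancy[:, j].astype(bool)
        n = int(bound.sum())
        k = int((bound & marked).sum())
        p = hypergeometric_overlap(U, K, n, k)
        tc: dict[str, int] = {}
        if traits is not None:
            for ts in (traits[i] for i in np.flatnonzero(bound & marked)):
                for t in ts:
                    tc[t] = tc.get(t, 0) + 1
        p_bonf = min(1.0, p * family)
        results.append(
            GWASResult(
                experiment_id=eid,
                U=U,
                K=K,
                n=n,
                k=k,
                fraction=(k / n) if n else 0.0,
                p_raw=p,
                p_bonf=p_bonf,
                significant=p_bonf < alpha,
                trait_counts=tc,
            )
        )
    results.sort(key=lambda r: (r.p_bonf, r.experiment_id))
    return results


def results_frame(results: list[GWASResult], meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabular view of GWAS results, optionally joined with manifest metadata."""
    df = pd.DataFrame(
        [
            {
                "experiment_id": r.experiment_id,
                "n": r.n,
                "k": r.k,
                "K": r.K,
                "U": r.U,
                "fraction": r.fraction,
                "p_raw": r.p_raw,
                "p_bonf": r.p_bonf,
                "significant": r.significant,
            }
            for r in results
        ]
    )
    if meta is not None:
        df = df.merge(
            meta[["experiment_id", "factor", "cell_type"]], on="experiment_id", how="left"
        )
        df = df[
            ["experiment_id", "factor", "cell_type", "n", "k", "K", "U",
             "fraction", "p_raw", "p_bonf", "significant"]
        ]
    return df
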