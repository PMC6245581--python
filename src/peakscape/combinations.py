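"""Combinatorial co-binding enrichment against a marginal-preserving null.

Within one cell type with N assayed factors, every region bound by at
least one factor carries an *exact binding pattern*: the precise subset of
factors binding it ("occupied only by Oct4, Sox2 and Nanog"), one of
2^N - 1 non-empty patterns. Observed pattern counts are scored against a
null ensemble of randomized matrices in which each factor column is
independently permuted over the M regions — so each factor keeps exactly
its observed number of binding events, while all co-binding structure is
destroyed.

For each pattern, the null mean and standard deviation over the ensemble
give z = (observed - mean) / sd, and the raw p-value is the upper tail of
the standard normal at z. A normal tail (rather than the empirical rank,
whose floor is 1/(n_rand+1)) is the only way a 100-draw ensemble can
express the astronomically small p-values that strongly co-bound factor
pairs produce; this approximation is deliberate and documented. Bonferroni
correction multiplies by the full family of 2^N - 1 patterns, counted
whether or not a pattern was ever observed. Only enrichment (upper tail)
is tested.

Patterns are encoded as integer bitmasks over the factor list: bit j set
means factor j binds. With N factors the counts of all patterns fit in a
length-2^N array indexed by bitmask (N is the number of *distinct factors*
in one cell type, small by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "select_combinatorial_cell_types",
    "pattern_counts",
    "randomize",
    "null_ensemble",
    "enrichment_test",
    "pattern_name",
]

MAX_FACTORS = 24  # 2^N count arrays; beyond this the dense tally is refused


def select_combinatorial_cell_types(
    manifest: pd.DataFrame, min_factors: int = 6
) -> list[str]:
    """Cell types with at least ``min_factors`` *distinct* factors assayed.

    Replicate experiments of one factor count once (they are collapsed by
    union of peaks before the cell-type matrix is built). Sorted by
    distinct-factor count descending, ties by name.
    """
    counts = manifest.groupby("cell_type")["factor"].nunique()
    sel = counts[counts >= min_factors]
    return list(sel.sort_index().sort_values(ascending=False, kind="mergesort").index)


def _as_binary(occ: np.ndarray) -> np.ndarray:
    occ = np.asarray(occ)
    if occ.ndim != 2:
        raise ValueError("occupancy must be 2-D")
    if occ.shape[1] > MAX_FACTORS:
        raise ValueError(f"more than {MAX_FACTORS} factors; dense pattern tally refused")
    return occ.astype(np.int64)


def _bitmasks(occ: np.ndarray) -> np.ndarray:
    """Per-row pattern bitmask (bit j = column j binds)."""
    N = occ.shape[1]
    weights = (1 << np.arange(N, dtype=np.int64))
    return occ @ weights


def pattern_counts(occ: np.ndarray, allow_empty_rows: bool = False) -> np.ndarray:
    """Count regions per exact binding pattern.

    Returns a length-2^N array ``counts`` with ``counts[m]`` = number of
    rows whose bitmask is m. For an observed cell-type matrix every row is
    bound by >= 1 factor, so an all-zero row is an error unless
    ``allow_empty_rows`` (randomized matrices may produce them; they tally
    as the empty pattern m=0 and never enter the 2^N - 1 family).
    """
    occ = _as_binary(occ)
    masks = _bitmasks(occ)
    if not allow_empty_rows and (masks == 0).any():
        raise ValueError("all-zero row in observed matrix (every region must be bound)")
    return np.bincount(masks, minlength=1 << occ.shape[1])


def randomize(occ: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each column over the rows.

    Column sums are exactly preserved (each factor keeps its number of
    binding events); equivalently each factor's bound-row set becomes a
    uniform random subset of its observed size.
    """
    return rng.permuted(np.asarray(occ), axis=0)


def null_ensemble(
    occ: np.ndarray, n_rand: int = 100, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Pattern counts over ``n_rand`` randomized matrices.

    Returns an (n_rand, 2^N) array. Each randomization is checked to
    preserve all column sums.
    """
    occ = _as_binary(occ)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    colsums = occ.sum(axis=0)
    out = np.empty((n_rand, 1 << occ.shape[1]), dtype=np.int64)
    for r in range(n_rand):
        rand = randomize(occ, rng)
        assert (rand.sum(axis=0) == colsums).all()
        out[r] = pattern_counts(rand, allow_empty_rows=True)
    return out


def pattern_name(mask: int, factors: list[str], sep: str = "+") -> str:
    return sep.join(f for j, f in enumerate(factors) if mask >> j & 1)


@dataclass
class PatternResult:
    pattern: int  # bitmask
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p_raw: float
    p_bonf: float
    degenerate: bool  # null sd was 0 while observed != null mean


def enrichment_test(
    observed: np.ndarray,
    ensemble: np.ndarray,
    factors: list[str] | None = None,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Score every non-empty pattern against the randomization null.

    ``observed`` is the length-2^N observed count array, ``ensemble`` the
    (n_rand, 2^N) null counts. The Bonferroni family size is 2^N - 1
    regardless of how many patterns were ever seen. By default only
    patterns observed or ever produced by the null are returned (the rest
    have observed = 0 and p_raw = 1); ``keep_all`` returns all 2^N - 1.
    Rows are sorted by (p_bonf, -observed, pattern).
    """
    observed = np.asarray(observed, dtype=np.int64)
    n_patterns = observed.shape[0]
    N = int(np.log2(n_patterns))
    family = n_patterns - 1
    mu = ensemble.mean(axis=0)
    sd = ensemble.std(axis=0, ddof=1)
    rows = []
    for mask in range(1, n_patterns):
        obs, m, s = int(observed[mask]), float(mu[mask]), float(sd[mask])
        if not keep_all and obs == 0 and m == 0.0:
            continue
        degenerate = False
        if s == 0.0:
            if obs == m:
                z, p = 0.0, 1.0
            else:
                z = np.inf if obs > m else -np.inf
                p = 0.0 if obs > m else 1.0
                degenerate = True
        else:
            z = (obs - m) / s
            p = float(stats.norm.sf(z))
        rows.append(
            {
                "pattern": mask,
                "pattern_name": pattern_name(mask, factors) if factors else str(mask),
                "n_factors": bin(mask).count("1"),
                "observed": obs,
                "null_mean": m,
                "null_sd": s,
                "z": float(z),
                "p_raw": p,
                "p_bonf": min(1.0, p * family),
                "degenerate": degenerate,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["p_bonf", "observed", "pattern"], ascending=[True, False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df


def cell_type_enrichment(
    occ: np.ndarray,
    factors: list[str],
    n_rand: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Full pattern-enrichment analysis for one cell type's factor matrix.

    ``occ`` must contain only rows bound by >= 1 factor (the cell type's
    own merged-region universe), with one column per distinct factor
    (replicates already collapsed by peak union).
    """
    observed = pattern_counts(occ)
    ens = null_ensemble(occ, n_rand=n_rand, seed=seed)
    return enrichment_test(observed, ens, factors=factors)
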