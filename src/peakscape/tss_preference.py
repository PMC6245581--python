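"""Per-experiment TSS-proximity preference profiles and cross-species comparison.

Each peak carries a signed distance to its nearest TSS (see
:mod:`peakscape.intervals`): 0 = the peak contains the TSS, negative =
upstream of the gene, positive = downstream. An experiment's *location
profile* is the triple of fractions (f_up, f_tss, f_down). Experiments
with more than half of their peaks on one side are classified as
upstream- or downstream-biased (the RNA-polymerase-III-like and
ZNF274-like archetypes); everything else is "balanced" and is displayed
sorted by the TSS-overlap fraction, from promoter factors (RNAPII-like,
f_tss > 0.8) down to distal factors (CTCF/MAFK-like, f_tss < 0.2).

The cross-species comparison takes, per factor present in both species,
the median f_tss over that factor's experiments (MAD as spread), and
reports the Pearson correlation plus an ordinary least-squares regression
of the second species on the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LocationProfile",
    "SpeciesComparison",
    "location_profile",
    "profiles_frame",
    "sort_profiles",
    "compare_species",
]

GROUP_UP = "upstream-biased"
GROUP_DOWN = "downstream-biased"
GROUP_BALANCED = "balanced"


@dataclass(frozen=True)
class LocationProfile:
    experiment_id: str
    f_tss: float
    f_up: float
    f_down: float
    n_peaks: int
    group: str


def location_profile(distances, experiment_id: str = "") -> LocationProfile:
    """Fractions of peaks overlapping (d=0), upstream (d<0) and downstream
    (d>0) of the nearest TSS.

    ``distances`` are signed bp distances; NaN entries (peaks on
    chromosomes without a TSS) are excluded from all three fractions.
    Raises if no peak has a defined distance.
    """
    d = np.asarray(distances, dtype=float)
    d = d[~np.isnan(d)]
    n = len(d)
    if n == 0:
        raise ValueError(f"experiment {experiment_id!r}: no peaks with defined distance")
    f_tss = float((d == 0).sum() / n)
    f_up = float((d < 0).sum() / n)
    f_down = float((d > 0).sum() / n)
    if f_up > 0.5:
        group = GROUP_UP
    elif f_down > 0.5:
        group = GROUP_DOWN
    else:
        group = GROUP_BALANCED
    return LocationProfile(experiment_id, f_tss, f_up, f_down, n, group)


def profiles_frame(profiles: list[LocationProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles])


def sort_profiles(profiles: list[LocationProfile]) -> dict[str, list[LocationProfile]]:
    """Split into display groups, sorting the balanced group by f_tss descending.

    Mirrors the stacked-bar figure layout: biased experiments are pulled
    into their own side panels; the main panel is the balanced continuum
    ordered by promoter-overlap fraction.
    """
    balanced = sorted(
        (p for p in profiles if p.group == GROUP_BALANCED),
        key=lambda p: (-p.f_tss, p.experiment_id),
    )
    return {
        GROUP_BALANCED: balanced,
        GROUP_UP: [p for p in profiles if p.group == GROUP_UP],
        GROUP_DOWN: [p for p in profiles if p.group == GROUP_DOWN],
    }


@dataclass
class SpeciesComparison:
    per_factor: pd.DataFrame  # factor, f_tss_a, f_tss_b, mad_a, mad_b, n_a, n_b
    pearson_r: float
    slope: float
    intercept: float


def _mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation (display spread, no 1.4826 factor)."""
    return float(np.median(np.abs(x - np.median(x))))


def compare_species(
    profiles_a: pd.DataFrame, profiles_b: pd.DataFrame
) -> SpeciesComparison:
    """Compare per-factor TSS-overlap fractions between two species.

    Inputs are profile tables with columns ``factor`` and ``f_tss`` (one
    row per experiment). Factors are matched case-insensitively (CFOS is
    cFos); a collision (two distinct names in one species mapping to the
    same key) is an error. Needs >= 3 shared factors for the correlation
    to be meaningful. The regression is of species-b medians on species-a
    medians.
    """

    def _collapse(df: pd.DataFrame, tag: str) -> pd.DataFrame:
        keys = df["factor"].str.upper()
        collide = df.groupby(keys)["factor"].nunique()
        collide = collide[collide > 1]
        if len(collide):
            raise ValueError(
                f"{tag}: factor names collide after case-normalization: "
                f"{sorted(collide.index)}"
            )
        g = df.assign(_key=keys).groupby("_key")["f_tss"]
        return pd.DataFrame(
            {"median": g.median(), "mad": g.apply(lambda s: _mad(s.to_numpy())), "n": g.size()}
        )

    a = _collapse(profiles_a, "species A")
    b = _collapse(profiles_b, "species B")
    shared = sorted(set(a.index) & set(b.index))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared factors; need >= 3")
    x = a.loc[shared, "median"].to_numpy()
    y = b.loc[shared, "median"].to_numpy()
    r = float(stats.pearsonr(x, y).statistic)
    fit = stats.linregress(x, y)
    per_factor = pd.DataFrame(
        {
            "factor": shared,
            "f_tss_a": x,
            "f_tss_b": y,
            "mad_a": a.loc[shared, "mad"].to_numpy(),
            "mad_b": b.loc[shared, "mad"].to_numpy(),
            "n_a": a.loc[shared, "n"].to_numpy(),
            "n_b": b.loc[shared, "n"].to_numpy(),
        }
    )
    return SpeciesComparison(per_factor, r, float(fit.slope), float(fit.intercept))
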