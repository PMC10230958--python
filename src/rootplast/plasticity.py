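"""Relative distance plasticity index (RDPI) and genotype contrasts.

For a genotype and trait, take every pair of observations made in two
*different* environments (P rates j and j') and form the relative distance

    rd = |x_i'j' - x_ij| / (x_i'j' + x_ij)   in [0, 1],

then average over the n retained pairs:  RDPI = (sum rd) / n.  Zero means no
plasticity (all cross-environment pairs equal), one is maximal.  The index
is a ratio, so it is invariant to rescaling the trait by a positive
constant; it is undefined for negative values.

Pairing unit: plot means.  Camera views and plants within a plot are not
independent, so pairing raw pseudoreplicates would inflate n and shrink
standard errors; tables at finer levels are averaged to plots first.

Six variants are computed per genotype and trait on a six-level P design:
``Total`` pools all C(6,2) = 15 unordered environment pairs, and ``P15`` ...
``P75`` restrict to pairs between one fertilized rate and the unfertilized
baseline.  Degenerate pairs with x + x' = 0 (both zero) are dropped and
counted; a pair with exactly one zero has rd = 1, the limit of the ratio.

Genotype comparisons use Welch's unequal-variance t-test on the per-pair
distance collections, and the trait-averaged contrast uses a paired t-test
across traits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trait_data import PhenotypeTable, aggregate

__all__ = [
    "DistanceSet",
    "RDPIResult",
    "relative_distances",
    "rdpi",
    "rdpi_variants",
    "compare_genotypes",
    "mean_rdpi_contrast",
]


@dataclass
class DistanceSet:
    """All cross-environment relative distances for one genotype x trait."""

    genotype: str
    trait: str
    env_pair: tuple[float, float] | None  # None for pooled sets
    distances: np.ndarray
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return int(self.distances.size)


@dataclass(frozen=True)
class RDPIResult:
    genotype: str
    trait: str
    variant: str
    rdpi: float
    se: float
    n_pairs: int


def _plot_values(table: PhenotypeTable, genotype: str, trait: str, env: float) -> np.ndarray:
    if table.level in ("view", "plant"):
        table = aggregate(table, "plot")
    df = table.data
    sel = df[(df["genotype"] == genotype) & (df["trait"] == trait) & (df["p_rate"] == env)]
    if sel.empty:
        raise ValueError(f"no observations for {genotype!r}/{trait!r} at P rate {env}")
    return sel["value"].to_numpy(dtype=float)


def relative_distances(
    table: PhenotypeTable,
    genotype: str,
    trait: str,
    env_a: float,
    env_b: float,
) -> DistanceSet:
    """Relative distances over all cross-environment plot-mean pairs."""
    if env_a == env_b:
        raise ValueError("env_a and env_b must differ (within-environment pairs are never counted)")
    a = _plot_values(table, genotype, trait, env_a)
    b = _plot_values(table, genotype, trait, env_b)
    if (a < 0).any() or (b < 0).any():
        raise ValueError(f"negative trait values for {trait!r}: relative distance undefined")
    s = a[:, None] + b[None, :]
    d = np.abs(b[None, :] - a[:, None])
    keep = s > 0
    rd = (d[keep] / s[keep]).ravel()
    return DistanceSet(
        genotype=genotype,
        trait=trait,
        env_pair=(env_a, env_b),
        distances=rd,
        n_dropped=int((~keep).sum()),
    )


def rdpi(dset: DistanceSet | Iterable[DistanceSet], variant: str | None = None) -> RDPIResult:
    """Mean relative distance over all retained pairs, with its standard error."""
    if isinstance(dset, DistanceSet):
        sets = [dset]
    else:
        sets = list(dset)
    if not sets:
        raise ValueError("no distance sets given")
    genotype = sets[0].genotype
    trait = sets[0].trait
    if any(s.genotype != genotype or s.trait != trait for s in sets):
        raise ValueError("cannot pool distance sets across genotypes or traits")
    rd = np.concatenate([s.distances for s in sets]) if sets else np.array([])
    if rd.size == 0:
        raise ValueError(f"RDPI undefined for {genotype!r}/{trait!r}: no retained pairs")
    se = float(rd.std(ddof=1) / np.sqrt(rd.size)) if rd.size > 1 else float("nan")
    if variant is None:
        variant = "Total" if len(sets) > 1 else _pair_name(sets[0].env_pair)
    return RDPIResult(
        genotype=genotype,
        trait=trait,
        variant=variant,
        rdpi=float(rd.mean()),
        se=se,
        n_pairs=int(rd.size),
    )


def _pair_name(pair: tuple[float, float] | None) -> str:
    if pair is None:
        return "Total"
    return f"P{pair[0]:g}-P{pair[1]:g}"


def rdpi_variants(
    table: PhenotypeTable,
    genotype: str,
    trait: str,
    baseline: float = 0.0,
) -> list[RDPIResult]:
    """The pooled-total RDPI plus one baseline-contrast RDPI per other level.

    On a six-level design this yields the six canonical variants: ``Total``
    over all 15 unordered level pairs and ``P15``..``P75`` for each
    fertilized rate against the unfertilized baseline.  A level absent from
    the data flags its variant absent rather than failing the rest.
    """
    levels = sorted(table.p_levels)
    if baseline not in levels:
        raise ValueError(f"baseline P rate {baseline} not present (levels: {levels})")
    all_sets = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            all_sets.append(relative_distances(table, genotype, trait, a, b))
    results = [rdpi(all_sets, variant="Total")]
    for lvl in levels:
        if lvl == baseline:
            continue
        dset = relative_distances(table, genotype, trait, baseline, lvl)
        results.append(rdpi(dset, variant=f"P{lvl:g}"))
    return results


def compare_genotypes(dset_g1: DistanceSet, dset_g2: DistanceSet) -> dict:
    """Welch two-sample t-test between two genotypes' distance collections.

    Returns the RDPI difference (genotype 2 minus genotype 1), the t
    statistic and the two-sided p-value.
    """
    d1, d2 = dset_g1.distances, dset_g2.distances
    if d1.size < 2 or d2.size < 2:
        raise ValueError("need >= 2 distances per genotype for a comparison")
    if np.array_equal(d1, d2):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(d2, d1, equal_var=False)
    return {
        "difference": float(d2.mean() - d1.mean()),
        "t": float(t),
        "p_value": float(p),
        "n_g1": int(d1.size),
        "n_g2": int(d2.size),
    }


def pooled_distance_set(sets: Iterable[DistanceSet]) -> DistanceSet:
    """Union of same-genotype, same-trait distance sets (the Total pool)."""
    sets = list(sets)
    if not sets:
        raise ValueError("no distance sets given")
    g, t = sets[0].genotype, sets[0].trait
    if any(s.genotype != g or s.trait != t for s in sets):
        raise ValueError("cannot pool distance sets across genotypes or traits")
    return DistanceSet(
        genotype=g,
        trait=t,
        env_pair=None,
        distances=np.concatenate([s.distances for s in sets]),
        n_dropped=sum(s.n_dropped for s in sets),
    )


def mean_rdpi_contrast(
    results_g1: Sequence[RDPIResult], results_g2: Sequence[RDPIResult]
) -> dict:
    """Percent difference of trait-averaged RDPI between two genotypes.

    Results are paired by trait; a paired t-test across traits gives the
    p-value.  Positive percent difference means genotype 2 is more plastic.
    """
    m1 = {r.trait: r.rdpi for r in results_g1}
    m2 = {r.trait: r.rdpi for r in results_g2}
    only1 = sorted(set(m1) - set(m2))
    only2 = sorted(set(m2) - set(m1))
    if only1 or only2:
        raise ValueError(f"trait sets differ: only in g1 {only1}, only in g2 {only2}")
    traits = sorted(m1)
    x1 = np.array([m1[t] for t in traits])
    x2 = np.array([m2[t] for t in traits])
    mean1, mean2 = float(x1.mean()), float(x2.mean())
    if mean1 == 0:
        raise ValueError("genotype-1 mean RDPI is zero; percent difference undefined")
    if np.allclose(x1, x2):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(x2, x1)
    return {
        "pct_difference": float(100.0 * (mean2 - mean1) / mean1),
        "mean_g1": mean1,
        "mean_g2": mean2,
        "t": float(t),
        "p_value": float(p),
        "n_traits": len(traits),
    }
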