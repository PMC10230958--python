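"""Synthetic multi-environment field-trial generator.

Emulates a two-run phosphorus dose-response trial on field-grown sorghum:
a randomized complete block design with 2 genotypes, six P rates
(0-75 kg P/ha), 2 runs, 2 blocks per run, 3 replicated plots per block, 6
plants per plot and 3 camera views per excavated root crown (the views are
pseudoreplicates, not independent samples).

Observations follow a fully random effects decomposition

    y = mu + g + p + gp + pr + gpr + prb + gprb + eps (+ run + g_run)

with every term drawn independently N(0, sigma2_term), realized once per
index combination and reused across the nested replicates it spans.  The
residual eps is realized once per *plot* (the replicated plot is the
experimental unit); camera views add measurement noise with one tenth of the
residual variance.  A deterministic genotype-specific asymptotic
dose-response mu_g(P) = A - B*exp(-c*P) can be added to the cell mean, which
is what drives plasticity downstream.  Multi-trait tables optionally share a
per-group latent factor with loading sqrt(group_rho), inducing correlation
group_rho between traits of the same group and zero across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trait_data import LONG_COLUMNS, PhenotypeTable, TraitRegistry

__all__ = [
    "DesignSpec",
    "DoseResponse",
    "SimParams",
    "SIGMA2_TERMS",
    "simulate_trial",
    "simulate_plasticity_contrast",
]

#: recognised variance-component keys and the design factors each spans
TERM_FACTORS: dict[str, tuple[str, ...]] = {
    "g": ("genotype",),
    "p": ("p_rate",),
    "gp": ("genotype", "p_rate"),
    "run": ("run",),
    "g_run": ("genotype", "run"),
    "pr": ("p_rate", "run"),
    "gpr": ("genotype", "p_rate", "run"),
    "prb": ("p_rate", "run", "block"),
    "gprb": ("genotype", "p_rate", "run", "block"),
    "eps": ("genotype", "p_rate", "run", "block", "plot"),
}

SIGMA2_TERMS: tuple[str, ...] = tuple(TERM_FACTORS)

#: fraction of the residual variance attached to each pseudoreplicate view
VIEW_NOISE_FRACTION = 0.1


@dataclass(frozen=True)
class DesignSpec:
    """Factor levels and replication counts of the trial."""

    n_genotypes: int = 2
    p_levels: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0)
    n_runs: int = 2
    n_blocks: int = 2
    n_plots: int = 3
    n_plants: int = 6
    n_views: int = 3
    genotype_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = (
            self.n_genotypes,
            len(self.p_levels),
            self.n_runs,
            self.n_blocks,
            self.n_plots,
            self.n_plants,
            self.n_views,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        if list(self.p_levels) != sorted(set(self.p_levels)):
            raise ValueError("p_levels must be strictly increasing")
        if self.genotype_labels is not None and len(self.genotype_labels) != self.n_genotypes:
            raise ValueError("genotype_labels length must equal n_genotypes")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.genotype_labels is not None:
            return self.genotype_labels
        return tuple(f"G{i + 1}" for i in range(self.n_genotypes))

    @property
    def n_observations(self) -> int:
        return (
            self.n_genotypes
            * len(self.p_levels)
            * self.n_runs
            * self.n_blocks
            * self.n_plots
            * self.n_plants
            * self.n_views
        )


@dataclass(frozen=True)
class DoseResponse:
    """Asymptotic mean response mu(P) = A - B*exp(-c*P)."""

    A: float
    B: float
    c: float

    def __call__(self, p: np.ndarray | float) -> np.ndarray | float:
        return self.A - self.B * np.exp(-self.c * np.asarray(p, dtype=float))


@dataclass(frozen=True)
class SimParams:
    """Generating parameters shared by all simulated traits.

    ``sigma2`` maps variance-component names (subset of :data:`SIGMA2_TERMS`)
    to nonnegative variances in squared trait units.  ``dose_response`` is
    either one curve applied to every genotype, or a mapping from genotype
    label to curve; ``None`` means no deterministic P response.
    ``group_rho`` in [0, 1) is the latent within-trait-group correlation.
    ``transform="exp"`` exponentiates the Gaussian response, giving strictly
    positive (log-normal) trait values as required by ratio-based plasticity
    indices.
    """

    mu: float = 100.0
    sigma2: Mapping[str, float] = field(
        default_factory=lambda: {"g": 4.0, "p": 2.0, "gp": 2.0, "eps": 1.0}
    )
    dose_response: DoseResponse | Mapping[str, DoseResponse] | None = None
    group_rho: float = 0.0
    transform: str = "identity"  # {"identity", "exp"}

    def __post_init__(self) -> None:
        unknown = sorted(set(self.sigma2) - set(SIGMA2_TERMS))
        if unknown:
            raise ValueError(f"unknown variance components: {unknown}")
        if any(v < 0 for v in self.sigma2.values()):
            raise ValueError("variance components must be nonnegative")
        if not 0.0 <= self.group_rho < 1.0:
            raise ValueError("group_rho must be in [0, 1)")
        if self.transform not in ("identity", "exp"):
            raise ValueError("transform must be 'identity' or 'exp'")


def _term_shape(design: DesignSpec, term: str) -> tuple[int, ...]:
    sizes = {
        "genotype": design.n_genotypes,
        "p_rate": len(design.p_levels),
        "run": design.n_runs,
        "block": design.n_blocks,
        "plot": design.n_plots,
    }
    return tuple(sizes[f] for f in TERM_FACTORS[term])


def _draw_effects(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    sigma2: float,
    group_idx: np.ndarray,
    n_groups: int,
    rho: float,
) -> np.ndarray:
    """Effects of one term for all traits, shape ``(*shape, n_traits)``.

    Same-group traits share a latent N(0,1) factor with loading sqrt(rho);
    the remainder is trait-specific, so same-group effects correlate at rho.
    """
    n_traits = group_idx.size
    latent = rng.standard_normal((*shape, n_groups))
    own = rng.standard_normal((*shape, n_traits))
    z = np.sqrt(rho) * latent[..., group_idx] + np.sqrt(1.0 - rho) * own
    return np.sqrt(sigma2) * z


def simulate_trial(
    design: DesignSpec,
    params: SimParams,
    traits: TraitRegistry | Sequence[str],
    seed: int | np.random.Generator | None = 0,
) -> PhenotypeTable:
    """Simulate a complete balanced trial for one or more traits.

    With all variances zero and no dose response the table is the constant
    ``mu``.  The same seed reproduces the identical table.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(traits, TraitRegistry):
        acronyms = traits.acronyms
        group_names = sorted({t.group for t in traits})
        group_idx = np.array([group_names.index(traits[a].group) for a in acronyms])
    else:
        acronyms = list(traits)
        group_idx = np.zeros(len(acronyms), dtype=int)
        group_names = ["all"]
    n_traits = len(acronyms)

    G, P, R, B, L = (
        design.n_genotypes,
        len(design.p_levels),
        design.n_runs,
        design.n_blocks,
        design.n_plots,
    )
    full = (G, P, R, B, L)
    # accumulate per-plot totals, broadcasting each term over the axes it spans
    y = np.full((*full, n_traits), float(params.mu))
    for term in SIGMA2_TERMS:
        s2 = float(params.sigma2.get(term, 0.0))
        if s2 == 0.0:
            continue
        eff = _draw_effects(
            rng, _term_shape(design, term), s2, group_idx, len(group_names), params.group_rho
        )
        # align term axes with the full (g, p, run, block, plot) grid
        axes = [("genotype", "p_rate", "run", "block", "plot").index(f) for f in TERM_FACTORS[term]]
        expand = [slice(None) if i in axes else None for i in range(5)]
        y = y + eff[tuple(expand)]

    # deterministic dose response added to the genotype x P cell mean
    if params.dose_response is not None:
        p_arr = np.asarray(design.p_levels, dtype=float)
        for gi, label in enumerate(design.labels):
            if isinstance(params.dose_response, Mapping):
                curve = params.dose_response.get(label)
            else:
                curve = params.dose_response
            if curve is not None:
                y[gi] += np.asarray(curve(p_arr))[:, None, None, None, None]

    # plants inherit the plot value; views add measurement noise eps/10
    s2_view = VIEW_NOISE_FRACTION * float(params.sigma2.get("eps", 0.0))
    shape = (*full, design.n_plants, design.n_views, n_traits)
    vals = np.broadcast_to(y[:, :, :, :, :, None, None, :], shape).copy()
    if s2_view > 0.0:
        vals += rng.normal(0.0, np.sqrt(s2_view), size=shape)
    if params.transform == "exp":
        vals = np.exp(vals)

    idx = pd.MultiIndex.from_product(
        [
            list(design.labels),
            list(design.p_levels),
            range(1, R + 1),
            range(1, B + 1),
            range(1, L + 1),
            range(1, design.n_plants + 1),
            range(1, design.n_views + 1),
            acronyms,
        ],
        names=list(LONG_COLUMNS[:-1]),
    )
    df = pd.DataFrame({"value": vals.reshape(-1)}, index=idx).reset_index()
    return PhenotypeTable(df.loc[:, list(LONG_COLUMNS)], design=design)


def simulate_plasticity_contrast(
    design: DesignSpec,
    params_low: SimParams,
    params_high: SimParams,
    traits: TraitRegistry | Sequence[str],
    seed: int | np.random.Generator | None = 0,
) -> PhenotypeTable:
    """Two-genotype trial with contrasting reaction norms.

    Genotype 1 follows ``params_low``'s dose response (e.g. flat: low
    plasticity) and genotype 2 follows ``params_high``'s (e.g. steep: high
    plasticity); all random-effect structure is taken from ``params_low``.
    """
    if design.n_genotypes != 2:
        raise ValueError("plasticity contrast requires exactly 2 genotypes")

    def _single(params: SimParams) -> DoseResponse | None:
        dr = params.dose_response
        if dr is None or isinstance(dr, DoseResponse):
            return dr
        raise ValueError("contrast parameter sets must carry a single dose-response curve")

    labels = design.labels
    merged = replace(
        params_low,
        dose_response={labels[0]: _single(params_low), labels[1]: _single(params_high)},
    )
    return simulate_trial(design, merged, traits, seed=seed)
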