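"""Phenotypic plasticity via the relative distance plasticity index.

For each genotype and trait, RDPI averages |x_a - x_b| / (x_a + x_b) over
all pairs of plot means observed under different P rates: 0 means no
plasticity, 1 maximal.  Six variants are computed: the total over all
environment pairs, and each fertilized rate against the unfertilized
baseline.  A steeper reaction norm gives a larger index.
"""

from rootplast import DesignSpec, DoseResponse, SimParams, simulate_plasticity_contrast
from rootplast.plasticity import (
    compare_genotypes,
    pooled_distance_set,
    rdpi_variants,
    relative_distances,
)

design = DesignSpec(genotype_labels=("red", "white"))
flat = SimParams(mu=50.0, sigma2={"eps": 0.3}, dose_response=DoseResponse(0.0, 0.0, 0.05))
steep = SimParams(mu=50.0, sigma2={"eps": 0.3}, dose_response=DoseResponse(15.0, 15.0, 0.05))
table = simulate_plasticity_contrast(design, flat, steep, ["TRL"], seed=5).aggregate("plot")

for genotype in ("red", "white"):
    results = rdpi_variants(table, genotype, "TRL", baseline=0.0)
    line = ", ".join(f"{r.variant} {r.rdpi:.3f}" for r in results)
    print(f"{genotype:6s} {line}")

levels = sorted(table.p_levels)
pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
sets = {
    g: pooled_distance_set(relative_distances(table, g, "TRL", a, b) for a, b in pairs)
    for g in ("red", "white")
}
cmp = compare_genotypes(sets["red"], sets["white"])
print(f"\nwhite - red total RDPI difference: {cmp['difference']:+.3f} "
      f"(Welch p = {cmp['p_value']:.2e})")
print(
    "\nThe white genotype's steep reaction norm yields the higher index in\n"
    "every variant, and the difference grows with the P contrast against the\n"
    "unfertilized baseline."
)
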