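# rootplast

Statistical toolkit for multi-environment **root-system-architecture (RSA)
field trials**: trait screening, broad-sense heritability, grouped
ordination, and phosphorus-response plasticity.

Field phenotyping of excavated root crowns ("shovelomics") produces dozens
of correlated traits — lengths, areas, volumes, diameters, counts, angles,
widths, biomass — measured across genotypes, fertilizer rates, runs,
blocks, replicated plots and pseudoreplicate camera views. `rootplast`
implements the full analysis cascade for such panels:

1. **Screening** — descriptive statistics per trait with the coefficient of
   variation CoV = 100·σ/x̄; traits are kept when CoV ≥ 30% and when a
   factorial ANOVA (`value ~ block stratum + genotype * P`, plot means as
   the error unit) finds a genotype difference at p < 0.05.
2. **Heritability** — variance components of the fully random model

   ```
   y = μ + g + p + gp + pr + gpr + prb + gprb + ε
   ```

   (genotype, P rate, run, block strata) estimated by expected mean squares
   or EM-REML, then broad-sense heritability on an entry-mean basis:

   ```
   H² = σ²_g / σ²_p ,   σ²_p = σ²_g + σ²_{g×t}/n + σ²_ε/(r·n)
   ```

   with n trials and r replicates per trial.
3. **Multiple factor analysis (MFA)** — each trait group's standardized
   block is divided by √λ₁ of its own PCA before a global PCA, so no group
   dominates; outputs eigenvalues, variable/group coordinates,
   contributions, cos², and the RV (∈[0,1]) and Lg association matrices,
   including each group's link to the consensus configuration.
4. **Plasticity (RDPI)** — the relative distance plasticity index
   `RDPI = (1/n) Σ |x_a − x_b| / (x_a + x_b)` over all same-genotype pairs
   of plot means in different P environments (0 = no plasticity,
   1 = maximal), in six variants (all environment pairs, and each
   fertilized rate against the unfertilized baseline), with Welch and
   paired-t genotype comparisons.
5. **Synthetic trials** — a generator that draws every random term of the
   model above with chosen variances, adds genotype-specific asymptotic
   dose responses `μ_g(P) = A − B·e^{−cP}`, and reproduces the published
   per-trait means and CoVs of a packaged 51-trait reference table, so the
   whole cascade is testable end to end.

The package is used from Python (see `examples/`), with a thin `rootplast`
command-line wrapper (`simulate`, `screen`, `heritability`, `mfa`, `rdpi`,
`run`) for shell pipelines.

## Worked example

Screening arithmetic on the packaged 51-trait summary table
(`examples/01_screen_published_table.py`):

```
traits in the table:            51
total root length CoV:          100 * 11438 / 24059 = 47.5%
eliminated by CoV < 30%:        13
CoV in [30%, 60%):              33
CoV >= 60%:                     5
survive CoV + genotype filters: 30
```

Thirteen low-variability traits (orientation, solidity, diameters, angle
frequencies, …) are dropped; of the 38 variable traits, 30 also differ
between the genotypes and proceed to heritability, ordination and
plasticity — exactly the set for which the packaged table reports H².

Heritability recovery on a simulated trial with known components
(`examples/03_heritability.py`, σ²_g = 4, σ²_g×p = 2, σ²_ε = 1):

```
anova_ems  components: {'g': 0.369, 'p': 0.031, 'gp': 1.005, 'gpr': 0.012, 'prb': 0.072, 'eps': 1.044}
           sigma2_p = 0.456,  H2 = 0.809
em_reml    components: {'g': 0.361, 'p': 0.019, 'gp': 0.998, 'prb': 0.008, 'gprb': 0.003, 'eps': 1.022}
           sigma2_p = 0.446,  H2 = 0.809
```

The two estimators agree (a balanced-design identity); with only two
genotypes the single genotype degree of freedom makes any one trial's σ̂²_g
noisy, which is why recovery claims are made over replicated simulations
(see `tests/test_acceptance.py`).

Plasticity contrast between a flat and a steep reaction norm
(`examples/05_rdpi.py`):

```
red    Total 0.007, P15 0.006, P30 0.008, P45 0.008, P60 0.007, P75 0.007
white  Total 0.054, P15 0.070, P30 0.102, P45 0.118, P60 0.124, P75 0.125

white - red total RDPI difference: +0.047 (Welch p = 0.00e+00)
```

## Layout

```
src/rootplast/      trait_data, synthetic_trial, screening, heritability,
                    mfa, plasticity, pipeline, cli
src/rootplast/data/ packaged 51-trait summary table (trait registry + fixture)
examples/           one short narrative script per capability
tests/              pytest suite incl. brute-force oracles (tests/_oracles.py)
docs/methods.md     models, conventions, calibration and limitations
```
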