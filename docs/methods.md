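# Methods

This note documents the statistical models, conventions and calibration
behind `rootplast`, the design choices where the design was genuinely open,
and what the validation suite does and does not demonstrate.

## Data model and analysis unit

Observations live in a tidy long table: one row per (genotype, P rate, run,
block, plot, plant, view, trait). Camera views are *pseudoreplicates* —
three perspectives of the same excavated root crown — and plants share a
plot; neither contributes independent error degrees of freedom. All
inferential stages (ANOVA, variance components, correlations, plasticity
pairing) therefore operate on **plot means**, obtained by averaging views
into plants and plants into plots. Aggregation is the arithmetic mean and
refuses silently unbalanced groups unless explicitly allowed; missingness
is handled by explicit row drops, never imputation.

The packaged 51-trait summary table doubles as the default trait registry
(acronym, trait group, unit, extraction mode, organ). Two conventions were
fixed on ingest: thousands separators are stripped, and the dispersion
column whose ratio to the mean reproduces the printed CoV (the third
numeric column) is treated as the SD, the other as the range — the printed
header order contradicts its own arithmetic, and the arithmetic wins. The
printed p-values "<0.001" are parsed to the numeric bound 0.001 with a
censoring flag; this cannot change any p < 0.05 screening decision. The
file is checksummed (SHA-256) and the loader fails on any modification.

## Trial model and the synthetic generator

The observation model is fully random:

    y_ijkl = μ + g_i + p_j + gp_ij + pr_jk + gpr_ijk + prb_jkl + gprb_ijkl + ε

with genotype i, P rate j, run k, block l, every term ~ N(0, σ²_term).
Optional `run` and `g_run` main/interaction components extend the model;
they default to zero in the generator but `g_run` is fitted by default
(see Heritability below). The generator realizes each term once per index
combination and reuses it across the replicates it spans. Because the
model carries no plot index, the residual ε is realized **once per plot** —
the replicated plot is the experimental unit — and pseudoreplicate views
add measurement noise with variance σ²_ε/10: views are perspectives of one
crown, so their dispersion must be well below between-plot dispersion; the
exact magnitude is a convention, not an estimate.

Multi-trait tables can share a per-group latent factor with loading
√ρ (ρ = `group_rho`): every random draw for a trait is
√ρ·z_group + √(1−ρ)·z_trait, so same-group traits correlate at ρ and
cross-group traits at 0. A deterministic genotype-specific dose response
μ_g(P) = A − B·e^{−cP} can be added to the cell mean; `transform="exp"`
exponentiates the Gaussian response for strictly positive (log-normal)
traits, which ratio-based plasticity indices require.

### Reference panel calibration

`simulate_reference_panel` emulates the packaged table's trial: genotypes
red/white, P ∈ {0, 15, 30, 45, 60, 75} kg P/ha, 2 runs × 2 blocks × 3
plots × 6 plants × 3 views. Per trait, values are exp(μ + dose(P) + noise)
with a half/half log-variance budget:

* the deterministic reaction norm d_g(P) = κ_g·s_n·(1 − e^{−0.05 P}),
  normalized so the 12-cell variance of the dose pattern equals the random
  log-variance s_n²; amplitude ratio κ_white : κ_red = 2.4 : 1.7, making
  the white genotype both higher-valued and distinctly more plastic — the
  between-genotype contrast the panel exists to emulate;
* random log-variance s_n² split across the model terms in fixed shares
  (g 0.20, gp 0.10, pr/gpr/prb/gprb 0.05 each, ε 0.50).

s_n is calibrated per trait by a 1-D root find so that the *expected* mean
and CoV equal the published values exactly
(E[X²]/E[X]² = (M₂/M₁²)·e^{s_n²} = 1 + cv², M_k the cell means of e^{k·d}).
Note that the *sample* CoV is a downward-biased estimator under strong
right skew, so realized sample CoVs for the heavy-tailed biomass traits
(target CoV > 60%) sit noticeably below target at n = 144 plots; this is a
property of the estimator, not of the generator.

The panel does **not** emulate spatial field trends, weather or soil
covariates, missing values, trait-specific correlation structure beyond
the group-latent construction, or non-multiplicative measurement error.
Tests passing on this panel show that the pipeline's algebra and decision
logic behave as specified under the stated random-effects structure; they
do not validate the biology of any real trial.

## Screening

* Summary statistics pool both runs; SD is the sample SD (n−1); CoV is
  undefined (flagged, not NaN-propagated) for nonpositive means.
* The CoV filter keeps CoV ≥ threshold (default 30%), boundary inclusive.
  Reporting bands quoted as "a% to b%" cover [a, b+1) at the printed
  1-decimal resolution.
* The factorial ANOVA fits `value ~ blockstratum(run/block) + genotype*P`
  on plot means of a balanced table, by direct sums-of-squares
  decomposition; F ratios use the plot-stratum residual. Unbalanced input
  is an error instructing aggregation, not a silent Type-I/II/III choice.
* The genotype filter uses strict p < α (default 0.05).
* Correlations are Pearson r on plot means with exact-t two-sided p;
  zero-variance traits yield flagged NaNs. No multiple-testing correction
  is applied at any screening stage, by design.

## Variance components and heritability

Two estimators over the model terms (default g, p, gp, g_run, pr, gpr,
prb, gprb plus the residual), fitted to plot means:

* **anova_ems** — ANOVA quadratic forms are built from the hierarchy of
  cell-mean projections; each expected mean square's coefficients are
  computed exactly as tr(A_t Z_k Z_kᵀ)/df_t and the linear system of
  observed = expected mean squares is solved, truncating negative
  estimates at zero (recorded). The moment equations are exact for any
  fitted model; the estimator coincides with REML on balanced data when
  the fitted terms form a complete orthogonal lattice and the optimum is
  interior.
* **em_reml** — the classical EM update
  σ²_k ← σ²_k + (σ²_k)²/q_k · (yᵀP Z_k Z_kᵀ P y − tr(Z_kᵀ P Z_k)) on the
  REML projection P of an intercept-only fixed part. The REML
  log-likelihood is nondecreasing across iterations (property-tested).
  Convergence is declared when the largest component change falls below
  1e-6 of the total fitted variance — a per-component relative criterion
  can never trigger for components decaying to the zero boundary, whose
  change shrinks only like 1/iteration. Non-convergence is flagged on the
  result and warned about, never silently returned.

Heritability uses the entry-mean phenotypic variance
σ²_p = σ²_g + σ²_{g×t}/n + σ²_ε/(rn). A strict-as-printed mode omitting
σ²_g exists behind a flag for comparison only; without the σ²_g term the
ratio σ²_g/σ²_p is unbounded, so the full form is the default. Because the
observation model has no genotype×run term, the genotype-by-trial variance
σ²_{g×t} is mapped to a fitted `g_run` component by default, with `gpr` as
the configurable alternative; neither mapping is asserted as uniquely
correct. r defaults to blocks × plots per run (= 6 for the reference
design) and n to the number of runs (= 2); both are arguments. H² is
clipped to [0, 1] with the clipping recorded; σ²_p = 0 leaves H² undefined
and flagged.

With two genotypes, σ̂²_g carries a single degree of freedom and is
intrinsically noisy per trial; recovery claims in the validation suite are
therefore made on replicate-averaged components (200 simulated trials,
ratio-of-means H²), the standard pooled estimator.

## Multiple factor analysis

Conventions, fixed and mutually consistent:

* active columns are centered and scaled to unit variance with divisor n,
  so the per-group first eigenvalue λ₁, the global eigenvalues and the Lg
  coefficient share one covariance convention;
* column weights 1/λ₁ of the column's group; global decomposition by SVD
  of the row-weighted (1/n), column-weighted matrix;
* axis signs are fixed by orienting each axis so its largest-magnitude
  loading is positive (SVD signs are otherwise arbitrary and would break
  reproducibility);
* variable coordinates are correlations with the axes; contributions are
  100·w_v·coord²/λ (summing to 100 per dimension); cos² uses the full-rank
  coordinate vector;
* the group coordinate on axis s equals Lg(group, axis s) and group
  coordinates sum to λ_s across groups;
* RV(X,Y) = tr(W_X W_Y)/√(tr W_X² · tr W_Y²) and
  Lg(X,Y) = tr(W_X W_Y)/(λ₁_X λ₁_Y) with W the observation-space
  cross-product operator; RV = Lg(X,Y)/√(Lg(X,X)·Lg(Y,Y)) holds by
  construction and is asserted to 1e-10. The "MFA" row/column of both
  matrices is the consensus: the weighted concatenation of all groups with
  its own first eigenvalue.
* categorical identifiers (genotype, P rate) are supplementary only,
  projected as barycenters of observation scores; they never shape the
  axes. The default observations are the 12 genotype × P cell means, but
  any row definition is accepted.
* the above-average contribution cutoff is 100/n_items percent.

Degenerate inputs fail loudly: constant active columns, all-zero groups,
and n_dims beyond the rank (truncated with a warning).

## Plasticity index

For a genotype and trait, every pair of plot means from two different P
environments contributes rd = |x_a − x_b|/(x_a + x_b) ∈ [0, 1]; the index
is the plain mean over retained pairs (the Valladares-style mean of
relative distances — the only form bounded in [0, 1]; some printed
renderings of the formula in the applied literature are typographically
garbled and are not followed). Conventions:

* pairing unit = plot mean; pairing raw pseudoreplicates would inflate the
  pair count and shrink standard errors;
* unordered environment pairs only; within-environment pairs never count;
* pairs with x_a = x_b = 0 are dropped (0/0) and counted; exactly one zero
  gives rd = 1, the limit of the ratio; negative values are an error (the
  index is undefined, use the log-normal generator option for positivity);
* six variants on a six-level design: Total pools all C(6,2) = 15 level
  pairs; P15 … P75 take one fertilized level against the unfertilized
  baseline (configurable).

Genotype comparisons use Welch's unequal-variance t-test on the per-pair
distance collections (the test is a convention; the distances within a
pool are not fully independent, so its p-values are approximate and are
validated by simulation calibration rather than assumed exact). The
trait-averaged contrast is a paired t-test across traits with the percent
difference of mean total RDPI.

## Pipeline

Stages run in a fixed order — CoV filter, then genotype filter, then
heritability, MFA and RDPI for the survivors only, mirroring a cascade in
which H² is reported exactly for the doubly screened traits. Stage outputs
are CSV/JSON; the manifest embeds the configuration, its hash and the
seed, and contains no timestamps, so identical configuration + seed reruns
are byte-identical. A stage failure aborts with the stage name while
preserving earlier outputs. The summary table renders magnitude-dependent
precision (≥1000 → whole numbers with thousands separators, else one
decimal; p-values as "<0.001" below that bound; H² as a dash for traits
filtered out before the heritability stage).

## Validation problem sizes

The suite's simulation scales were chosen as the smallest sizes at which
the Monte-Carlo error is comfortably below the asserted tolerances:
variance-component recovery over 200 trials at the reference design
(bias < 10% per generated component; pooled H² within 0.1); ANOVA type-I
calibration over 1,000 null trials (rejection within 3–7% at α = 0.05);
plasticity-contrast power over 200 low-noise runs (≥ 95% detection); MFA
and RDPI brute-force oracle equivalence on 5–100 random small instances at
1e-8/exact tolerances. Hypothesis-based property tests run derandomized.

## Known limitations

* No average-information REML, no standard errors for variance components,
  no narrow-sense heritability (no pedigree or marker data).
* ANOVA and EMS require balanced plot-level data; unbalanced designs are
  supported only through EM-REML.
* MFA handles quantitative active groups only; active categorical groups
  (MCA weighting) are out of scope, as are bootstrap ellipses and plots.
* RDPI inference treats pairwise distances as a sample; a mixed-model
  formulation of plasticity is not provided.
* The reference panel is a statistical stand-in calibrated to published
  summary moments; it cannot reproduce trait-level results of any real
  trial, only the structure of the analysis.
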