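# Methods

## Model and simulation design

The package studies a two-stage genomic-prediction workflow for testcross
field trials. Plot yields are generated from

    y_ijk = φ + γ_k + b_jk + g_i + e_ijk                (single trial)
    y_ijkl = φ + t_l + r_kl + b_jkl + g_i + e_ijkl       (multi-trial)

with replicate effects γ_k fixed in the single-trial model, trial t_l and
trial×replicate r_kl random in the multi-trial model, incomplete-block
effects b ~ N(0, σ_b²) and plot errors e ~ N(0, σ_e²). Breeding values
are g = Zu with marker effects u ~ N(0, σ_u² I_p) and Z the n×p matrix of
SNP covariates coded +1 (A1A1), −1 (A2A2) and 0 (heterozygous or
missing), so var(g) = G = ZZᵀσ_u².

Stage 1 fits the plot data with genotype as a fixed effect (check
varieties get their own fixed levels and are dropped from the output) and
returns BLUEs p with their variance-covariance matrix Ω. Stage 2 treats
the BLUEs as having iid errors R = Iσ_e², exactly as the two-stage
simplification prescribes; Ω is consumed only where a method explicitly
needs it (the BLUE-based heritability and the independent-genotype fit,
below).

### Scenario presets

`scenario1`/`scenario2` use the 177-genotype, 275-marker alpha-design
geometry (10 blocks of 18 plots, 2 replicates; 177 entries leave 3
surplus plots per replicate, filled with check entries excluded from
stage 2). `scenario3`/`scenario4` use the 698-genotype lattice-square
geometry; in the default genotyped-only mode the 698 lines occupy seven
10×10 trials with two replicates, and an optional mode
(`include_nongenotyped: true`) adds 202 non-genotyped lines with iid
N(0, σ_g2²) effects on a nine-trial layout (1800 plots, 2.1% of yields
missing completely at random, matching 38 of 1800). Scenarios 2 and 4
divide the marker variance of 1 and 3 by ten. All components are encoded
in the YAML presets and taken as given.

### Synthetic marker panels

The reference marker matrices are proprietary, so a generator emulates
doubled-haploid biallelic SNPs: each marker's allele frequency is drawn
uniformly on [0.05, 0.5] (biparental DH populations have intermediate
frequencies; the real spectra are unknown and configurable), calls are
homozygous per that frequency, then flipped to heterozygous (default 1%)
or missing (default 2%) to emulate genotyping artefacts. Markers are
unlinked: every estimator consumes Z only through ZZᵀ, and no LD
structure is specified for the real panels; a crude block-correlation
mode exists but is off by default. QC mirrors standard practice with
strict inequalities: markers with more than 20% missing calls, more than
5% heterozygous calls, or minor-allele frequency below 2.5% are removed
(MAF computed on non-missing calls, heterozygotes contributing one copy
of each allele). Because the panel is synthetic and unlinked, the
absolute values of published real-data tables are out of reach; what the
tests check is the estimators' *relative* behaviour (bias direction,
MSD ordering, boundedness, degeneracy handling), which does transfer.

## REML engine

Variance components are estimated by maximizing the restricted
log-likelihood on the observation scale. Models with one random term plus
an iid residual (the stage-2 fits, the single-trial stage-1 model, all
cross-validation training fits) use a spectral path: eigendecompose the
covariance kernel once, profile the residual variance out, and search the
variance ratio on a log grid (33 points spanning 16 decades around the
kernel scale) refined by bounded scalar minimization. Multi-component
models (multi-trial stage 1) use L-BFGS-B on log variances with analytic
gradients; near-singular V is repaired with a 1e-10 relative ridge so the
line search always sees a finite value and gradient. Convergence uses a
relative tolerance of 1e-8 with at most 200 iterations; estimates below
1e-8 of the phenotypic variance are returned as exactly 0 with a boundary
flag, enforcing the zero lower boundary of σ̂_u². Non-convergence is
flagged, never raised, because the evaluation layer counts failures per
dataset. Fixed-effect blocks use a pseudo-inverse with rank tolerance
1e-10 relative to the largest singular value; linearly dependent
non-genotype columns (confounded design effects) are dropped before
fitting, and a dependent genotype column marks the design disconnected.

## The estimators

Sample moments use the n−1 denominator throughout; P_u =
(I_n − J_n/n)/(n−1) is the operator with gᵀP_u g the sample variance of
g, and trace(P_u A) is evaluated as (trace A − sum(A)/n)/(n−1) without
forming P_u.

**Heritabilities.** H²_m1 = σ̂_g²/(σ̂_g² + σ̂_e²/r) with the stage-1 plot
error and r replicates; H²_m2 = σ̂_g²/(σ̂_g² + ῡ/2) with ῡ the mean
variance of a difference of two BLUEs, computed from Ω as
(2/(n(n−1)))·(n·trace Ω − sum Ω); H²_m3 = 1 − ῡ_BLUP/(2σ̂_g²), which can
be negative and is undefined (breakdown) at σ̂_g² = 0;
H²_m4 = trace(P_u G)/(trace(P_u G) + trace(R P_u)); H²_m5 is the square
of the Method-5 accuracy. The σ̂_g² of Methods 1–3 comes from the
independent-genotype stage-2 fit.

**Independent-genotype fit.** On the means scale an iid genetic variance
and an iid residual are not jointly identifiable (both are ∝ I), so the
fit holds the stage-1 Ω fixed as the error structure, V = Iσ_g² + Ω, and
REML-estimates the single free component — the standard weighted
two-stage formulation. The reported effective means-scale error variance
is ῡ/2, which reduces to σ_e²/r on a balanced complete-block design and
makes the BLUP shrink exactly by σ̂_g²/(σ̂_g² + σ_e²/r) there. ῡ_BLUP is
the mean prediction-error variance of a difference of two genotype BLUPs,
taken from the genotype-scale PEV matrix G − GPG.

**Accuracies.** Methods 1–4 divide the cross-validated ability by √H²;
H² ≤ 0 raises a breakdown flag instead of a value. Method 5 evaluates
trace(P_u CG)/√(trace(P_u G)·trace(Cᵀ P_u C V)) with C = GV⁻¹Q and
Q = I − 1(1ᵀV⁻¹1)⁻¹1ᵀV⁻¹; if trace(P_u G) falls below 1e-12 of
trace(P_u V) the genetic signal is degenerate and 0 is returned with a
flag. Method 6 rescales the fold-wise cross-validation covariance:
s(ĝ,p)/√(s²(ĝ)·trace(P_u G)), where trace(P_u G) is computed once per
dataset from the full-data RR-BLUP fit and the fold-wise values are
averaged. Method 7 computes per-genotype reliabilities from the MME on
the genotype scale: var(ĝ) = cov(g, ĝ) = G − C22 with C22 = G − GPG
(algebraically identical to Z C22 Zᵀ of the marker-scale equations, but
never forming a p-dimensional system), ρ̂_i² = var(ĝ)_ii/var(g)_ii, and
returns the square root of their mean; genotypes with negligible genetic
variance are skipped. All estimators keep the untruncated value alongside
the [0, 1]-truncated one, with overshoot/undershoot flags; all are
invariant to a common positive rescaling of (p, G, V).

**Plug-in convention.** Every estimator uses the REML estimates
(σ̂_u², σ̂_e²) inside G and V. Heritability is computed once per dataset
from the full-data fits, not per cross-validation fold; the fold-wise
abilities are averaged first and divided by √H² once.

## Cross-validation

Entries are partitioned into k = 3 nearly balanced random folds,
replicated 5 times (15 splits). Variance components are re-estimated
within every training set; validation entries are predicted through the
cross-covariance block ĝ_v = Z_v Z_tᵀ σ̂_u² V_tt⁻¹(p_t − 1φ̂), so no
validation information reaches the training fit. The dataset-level
ability averages the fold-wise Pearson correlations (the published
wording is ambiguous between fold-wise and pooled; a pooled-predictions
mode is available via `ability_mode="pooled"`). Folds whose training fit
degenerates, or with fewer than three validation entries, are excluded
and counted.

## Evaluation bookkeeping

Per scenario, one marker panel and one layout are generated and shared
across all datasets (mirroring the reuse of a real panel across
simulations; `marker_mode="per-dataset"` regenerates instead). Datasets
with undefined or negative true accuracy (zero-variance BLUPs) and
datasets whose models fail to converge are excluded. Summary statistics
and MSD = Σ(est − truth)²/N use the common complete-case set so all
methods are compared on the same N; the true-accuracy benchmark is never
truncated, only estimates are. Between-method comparisons use plain
paired two-sided t-tests with Bonferroni correction over the seven
methods — a deliberate simplification of simulation-adjusted multiplicity
corrections.

## Problem sizes used in tests and the acceptance script

The shipped presets declare 1000 datasets per scenario, the study-scale
condition. The test suite and `scripts/acceptance.py` run the package's
own reduced-size replications: 100 scenario-1 datasets for the MSD
ranking, 200 for REML recovery (medians of σ̂_e² and σ̂_u² at the full
177×275 geometry), and 2000 Monte-Carlo draws on a fixed 100×200 panel
for the Method-5/7 oracles. These sizes give Monte-Carlo error well below
the assertion tolerances while keeping a full run within minutes on one
CPU.

## Known limitations

- Markers are unlinked and populations unstructured; real biparental DH
  panels carry strong LD and relatedness, which shifts the absolute
  heritability and ability levels (the indirect methods sit further below
  the truth here than with real panels, though the qualitative ranking of
  methods is unchanged).
- No spatial (row-column/AR1) error structures; the plot-basis
  heritability of Method 1 is not meaningful under spatial analysis.
- Stage 2's iid-error simplification discards the off-diagonal
  information in Ω except where a method explicitly uses ῡ.
- REML tolerances and algorithms are the package's own choices; other
  mixed-model software will differ in the last digits and occasionally in
  boundary behaviour.
- Arbitrary pedigrees, sparse solvers for very large n, and Bayesian
  alternatives to REML are out of scope.
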