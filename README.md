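# gsacc

Simulation benchmarking of estimators of **genomic-prediction accuracy** —
the correlation r(g, ĝ) between true and predicted breeding values — under
ridge-regression BLUP (RR-BLUP), for plant-breeding field trials.

## The problem

Genomic selection predicts the breeding value of a line from genome-wide
SNP markers, g = Zu with iid marker effects u ~ N(0, σᵤ²Iₚ), so that
var(g) = ZZᵀσᵤ². The quantity a breeder cares about is the accuracy
r(g, ĝ), but g is unobservable in real data. Practitioners therefore
estimate accuracy indirectly — dividing the cross-validated *predictive
ability* r(ĝ, p) by the square root of a heritability estimate — or
directly from the fitted mixed model. This package implements seven such
estimators and the simulation machinery needed to benchmark them against a
simulated truth:

- **synthetic doubled-haploid marker panels** (`gsacc.genomes`): homozygous
  ±1 calls with configurable MAF spectrum, heterozygous/missing artefact
  rates, and the standard QC rules (markers with >20% missing, >5%
  heterozygous calls, or MAF < 2.5% are discarded);
- **field-trial simulation** (`gsacc.trial_sim`): resolvable alpha designs
  (incomplete blocks nested in complete replicates) and multi-trial
  lattice-square layouts, with yields
  y = φ + replicate + trial + block + g + e;
- **two-stage REML analysis** (`gsacc.lmm`): stage 1 estimates adjusted
  genotype means (BLUEs) p with their variance-covariance matrix Ω; stage 2
  fits the means by RR-BLUP, V = ZZᵀσᵤ² + Iσₑ², giving
  ĝ = GV⁻¹(p − 1φ̂) and the mixed-model-equation blocks;
- **the seven estimators** (`gsacc.estimators`), with cross-validation in
  `gsacc.cv`:

| Method | Type | Estimator |
|---|---|---|
| 1 | indirect | r(ĝ,p)/H with H² = σ_g²/(σ_g² + σₑ²/r) (standard plot-basis) |
| 2 | indirect | H² = σ_g²/(σ_g² + ῡ/2), ῡ = mean variance of a BLUE difference |
| 3 | indirect | H² = 1 − ῡ_BLUP/(2σ_g²), from BLUP prediction-error variances |
| 4 | indirect | H² = trace(P_u G)/trace(P_u V) (expected variance ratio) |
| 5 | direct | trace(P_u CG)/√(trace(P_u G)·trace(Cᵀ P_u C V)), C = GV⁻¹Q |
| 6 | direct | s(ĝ,p)/√(s²(ĝ)·E[s_g²]) with E[s_g²] = trace(P_u G) |
| 7 | direct | √(mean reliability), ρᵢ² = var(ĝ)ᵢᵢ/var(g)ᵢᵢ from the MME |

Here P_u = (I − J/n)/(n−1) is the sample-variance operator and Q the
fixed-effect projector. Methods 1–4 require 3-fold cross-validation
replicated 5 times (15 splits); Methods 5 and 7 need no cross-validation.
The scenario runner (`gsacc.study`) simulates N datasets per scenario,
applies the exclusion and [0, 1]-truncation bookkeeping, and reports
per-method descriptive statistics and the mean squared deviation (MSD)
from the simulated truth.

Four shipped scenario presets (`scenario1`..`scenario4`) encode the
variance components of two reference maize data sets — a 177-line panel
with 275 SNPs in an alpha design (σᵤ² = 0.2019, σ_b² = 69.9089,
σₑ² = 48.6728) and a 698-line panel with 11 646 SNPs in lattice-square
trials — with the marker variance divided by ten in scenarios 2 and 4.
The original marker matrices are proprietary, so the synthetic DH panel
stands in for them; absolute published table values are therefore not
reproduced, but the qualitative behaviour of the estimators is.

## Worked example

```sh
gsacc run --scenario scenario1 --n-datasets 3 --seed 3 --out scratch/demo
```

prints (M0 is the simulated true accuracy; estimates truncated to [0, 1]):

```
method  N   MIN  MEAN   MAX   STD   MSD    Q1  MEDIAN    Q3
    M0  3 0.814 0.825 0.836 0.011 0.000 0.820   0.826 0.831
    M1  3 0.466 0.541 0.605 0.070 0.084 0.508   0.550 0.578
    M2  3 0.475 0.550 0.614 0.071 0.078 0.518   0.561 0.588
    M3  3 0.473 0.548 0.613 0.071 0.080 0.515   0.558 0.585
    M4  3 0.490 0.542 0.585 0.048 0.081 0.520   0.550 0.568
    M5  3 0.789 0.829 0.881 0.047 0.001 0.804   0.818 0.849
    M6  3 0.492 0.546 0.593 0.051 0.079 0.522   0.552 0.573
    M7  3 0.725 0.764 0.815 0.046 0.005 0.739   0.752 0.784
```

The direct methods 5 and 7 track the true accuracy closely (MSD 0.001 and
0.005) while the cross-validation-based methods underestimate it on this
synthetic panel. The run also writes `records.csv` (one row per simulated
dataset with all estimates, untruncated copies and status flags),
`heritability.csv`, `pairwise_corr.csv`, `events.csv` (overshoot /
undershoot / breakdown counts) and `ttests.csv`. From Python, the same
pipeline is available as `gsacc.run_scenario(load_scenario("scenario1"),
n_datasets=..., seed=...)`.

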