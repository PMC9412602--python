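# Methods

## Setting and assumptions

`ironmr` implements two-sample Mendelian randomisation with summary-level
data. Genetic variants serve as instrumental variables for an exposure
under the three IV premises: each variant is (1) robustly associated with
the exposure, (2) independent of exposure–outcome confounders, and (3)
associated with the outcome only through the exposure. Premise (1) is
enforced operationally (genome-wide significance, F ≥ 10); (2) and (3) are
unverifiable and are probed by the sensitivity suite (Egger intercept,
Cochran's Q, leave-one-out, funnel tables) rather than assumed away.
Exposure and outcome effects are taken from non-overlapping samples and
combined at the summary level; all estimators treat the J instruments as
independent (LD pruning upstream is what buys this).

## Instrument processing

Selection keeps variants with p strictly below `p_select` (default
5×10⁻⁸). LD pruning is greedy by ascending p-value: a variant is dropped
when its r² with any already-kept variant reaches `ld_r2` (default 0.01);
pairs missing from the user-supplied LD table are treated as unlinked and
recorded. When the outcome GWAS lacks a selected variant, the best proxy
with r² > `proxy_r2` (default 0.8) substitutes, breaking ties by smaller
p then rsID; the proxy's own effect sizes are used unchanged and its
provenance is kept in `proxy_of`. Harmonisation aligns the outcome record
to the exposure's effect allele, flipping sign and EAF for swapped
alleles and resolving strand flips through base complementation;
palindromic (A/T, C/G) variants are dropped because their strand cannot
be resolved from alleles alone — no EAF-window rescue is attempted.
Instrument strength uses F = (β/se)², the summary-data approximation; an
R²-based form F = R²(n−2)/(1−R²) with R² = 2·EAF(1−EAF)β² is available
when a sample size is supplied. The bundled instrument table prints F
values that neither form reproduces from the printed β/se (e.g. 256
printed vs 163 recomputed for the top ferritin variant); the printed
column is therefore carried as `f_reported` for reference and all
filtering uses the recomputed (β/se)², which comfortably clears the
conventional F ≥ 10 bound for all 12 variants.

## Estimators

Per-SNP Wald ratios use the first-order delta SE `se_y/|beta_x|` by
default — the convention of the standard two-sample toolchains, and the
choice that reproduces their p-values; the second-order form adding the
exposure-side variance is available by flag. Fixed-effect IVW pools
ratios with inverse-variance weights and uses normal p-values; the
multiplicative random-effect variant inflates the SE by max(1, √(Q/(J−1))).
MR-Egger regresses outcome on exposure effects with an intercept, weights
1/se_y², after orienting every beta_x non-negative; inference is t with
J−2 degrees of freedom and an estimated residual scale (equivalently,
weighted least squares with multiplicative overdispersion). The weighted
median interpolates the weight-ordered ratio estimates at cumulative
weight 0.5 (cumulative midpoints s_j = Σ_{i≤j} p_i − p_j/2); its SE is
the standard deviation over `n_boot` (default 5000) parametric-bootstrap
replicates drawing β_X and β_Y from normals with the reported SEs — the
seed is mandatory so pipelines are reproducible. Odds ratios are
exp(θ ± z·se). When the outcome betas come from a linear model on a 0/1
trait (as in the bundled data), these are exp(β)-per-SD without
case-prevalence rescaling; they hug 1.0 and are presented as such.

## Sensitivity diagnostics

Cochran's Q uses first-order weights fixed at their full-set values, with
per-SNP contributions summing to Q exactly; p from χ²(J−1). Leave-one-out
refits fixed-effect IVW J times; with J = 2 the reduced fits collapse to
Wald ratios, which is permitted. Funnel data are exported as
(ratio, precision) tables; symmetry is inspected, not tested — on the
bundled data, as in the source study, asymmetry is judged visually.

## Bayesian model averaging

Each non-empty subset S of the K candidate factors is a model. On the
weighted scale (x̃ = β_X/se_y, ỹ = β_Y/se_y per instrument row) the
marginal likelihood is ỹ ~ N(0, I_J + σ²X̃_S X̃_Sᵀ), evaluated through
the Woodbury identity so only |S|×|S| systems are solved; the test suite
checks this closed form against dense multivariate-normal log-densities
to 1e-8. Prior model probability is p^|S|(1−p)^{K−|S|} with p = 0.1 and
σ = 0.5 as defaults (both mandatory in the pipeline config so runs are
self-documenting). Posterior probabilities are normalised over the
enumerated space — the empty model is excluded because only
factor-containing models are ranked. Conditional estimates are ridge
posterior means (X̃_SᵀX̃_S + σ⁻²I)⁻¹X̃_Sᵀỹ. MIP_k sums the PPs of models
containing factor k; MACE_k is the PP-weighted average of its conditional
estimates. Exposure columns are weighted by 1/se_y only and *not*
re-standardised; implementations that scale risk-factor columns will give
different σ-dependent quantities, so scale inputs first when comparing.

Per-variant diagnostics use the highest-PP model: Q_j = (ỹ_j − ŷ_j)² with
ŷ from the ridge fit, and Cook's distance from the unpenalised weighted
regression on the same subset. Iterative exclusion removes one worst
offender per pass — first variants with Q above `q_max` (default 10),
then variants with Cook's distance above the median of F(|S|, J−|S|)
(flag-overridable) — refitting after each removal and stopping before the
instrument count would drop to the factor count. Permutation p-values
(not run by default) permute the outcome rows across instruments and
report the add-one-smoothed fraction of permutations whose MIP reaches
the observed value.

On the bundled 12-instrument table with the default priors, ferritin's
MIP is 0.774 against 0.771 in the source study and all four factor ranks
agree, which pins down the scaling convention. Two published magnitudes
are *not* recoverable from the printed inputs and are documented rather
than targeted. First, the per-variant Q of rs651007 is reported as
exceeding 10, but on the printed table Q(rs651007) = (ỹ − ŷ)² is bounded
by ỹ² = 10.67 (attained only at a zero fit) and any fitted model built
from the printed ferritin coefficients leaves it near 7.7; the published
value must reflect unprinted inputs (non-significant cross-biomarker
exposure effects, which the bundled matrix necessarily sets to zero, or a
different outcome-GWAS version — the source describes its outcome sample
inconsistently as 1088/360,106 and 1405/359,789 cases/controls).
rs651007 is nevertheless the worst-fitting variant by a wide margin (7.74
vs 1.83 for the runner-up). Second, as a consequence, the Q-phase of
iterative exclusion removes nothing at `q_max` = 10 on the bundled table;
the Cook phase does flag the variants the source flags (rs1800562 first,
Cook's d 0.664 over the 0.486 median-F threshold).

## Multivariable MR

Direct effects come from weighted least squares of β_Y on all K exposure
columns jointly (weights 1/se_y², no intercept), SEs from the weighted
normal equations with estimated scale, p-values from t(J−K). A
rank-deficient design raises a collinearity error naming the offending
exposures; otherwise the condition number of the weighted design and
per-exposure VIFs are reported. With K = 1 the point estimate coincides
with fixed-effect univariable IVW (the SE additionally carries the
estimated scale). The source study's multivariable table used an external
outcome GWAS and unstated per-exposure instrument subsets, so it is
reproduced structurally (schema, diagnostics) and validated by simulation
with planted direct effects, not numerically.

## Synthetic data

The generator draws per-factor exposure effects from N(0, 0.1²)
truncated to |β_X| > 0.05 (half the scale) so no instrument is vacuously
weak, EAFs from U(0.05, 0.95), and allele pairs that avoid palindromes
unless a scenario asks for them (to exercise the palindrome filter). True
outcome effects are γ_j = Σ_k θ_k β_Xjk + α_j. Balanced pleiotropy draws
α ~ N(0, sd) for a random `invalid_fraction` of variants; directional
pleiotropy draws α ~ N(mean, sd) *aligned with the exposure-increasing
allele* — allele coding is arbitrary, and without this alignment the IVW
bias term Σβ_Xα/Σβ_X² has expectation zero under symmetric coding, i.e.
the scenario would silently degenerate to balanced pleiotropy. Observed
summary statistics add N(0, se²) noise on both sides; measurement SEs
default to 0.01 on each side, typical of well-powered biomarker GWAS on
the SD scale. Identical seeds give bit-identical tables.

What the generator does not emulate: LD between instruments, allele-
frequency-dependent power, winner's curse from in-sample selection,
sample overlap between exposure and outcome studies, and binary-trait
outcome link functions. Passing tests therefore demonstrate estimator
correctness and calibration under the stated generative model, not
robustness to those real-data complications.

## Test problem sizes and numerical choices

The calibration checks use study sizes chosen to keep Monte-Carlo error
well below the asserted tolerances: IVW type-I error over 1000 null
replicates at J = 20; weighted-median robustness over 500 replicates at
J = 200 with 30% invalid instruments given directional pleiotropy of mean
0.02 (comparable to the median per-SNP outcome effect θ·E|β_X| = 0.02)
and sd 0.01; IVW and MVMR coverage over 500 and 100 replicates with
exposure-side SE 0.002 so the first-order ratio carries no material
regression dilution (with the default 0.01 the attenuation is ~1%, an
estimator property the coverage checks are not meant to absorb).
P-values printed beyond double range (one transferrin association is
quoted at 10⁻⁶¹⁰) underflow on parse and are clamped to the smallest
positive normal float, preserving strict-inequality selection. Ties in
LD pruning and proxy search break deterministically (p-value, then rsID).
All reported quantities in the study pipeline are deterministic given the
config and seed; re-runs are byte-identical.

## Known limitations

- The bundled table prints only effect alleles; other alleles are
  conventional fixture metadata (one palindromic truth, rs1799945 C/G, is
  replaced by C/T so the published "no palindromes removed" flow holds).
- Exposure betas for SNP×factor pairs below genome-wide significance are
  unpublished and enter the model-averaging matrix as zeros; this is the
  main suspected source of the per-variant-Q magnitude gap above.
- No multiple-testing adjustment is applied across the four biomarkers,
  matching the source presentation; p-values are nominal.
- Binary-exposure runs report estimates per unit log-odds liability with
  an explicit caveat banner; competing-risk bias is not modelled.
- MR-PRESSO, mode-based estimators, Steiger filtering, Egger
  heterogeneity (Rücker) model selection and LD estimation from reference
  panels are out of scope.
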