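# Methods

This note documents the statistical model behind `mrlink`, the defaults
and why they were chosen, what the simulator does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Model and assumptions

The package implements two-sample summary-data MR. For instrument j,
β̂Xj and β̂Yj are the estimated per-allele effects on exposure and
outcome from non-overlapping GWAS samples, with standard errors seXj and
seYj treated as known. Under the instrumental-variable assumptions
(relevance, exchangeability, exclusion restriction) each ratio
β̂Yj/β̂Xj estimates the same causal slope β. Estimator-specific
relaxations: MR-Egger requires only that pleiotropic effects be
independent of instrument strength (InSIDE); the weighted median
requires ≥ 50% of the inverse-variance weight on valid instruments; the
mode estimators require the largest homogeneous cluster of ratios to be
valid. Exposure-side uncertainty is ignored in the analytic SEs (the
NO-Measurement-Error approximation, reasonable at F ≫ 10) but is
propagated in the parametric bootstrap used for median/mode SEs and in
MR-PRESSO's resampling.

For binary outcomes all effects are log odds ratios; quantitative-trait
betas are treated as SD-standardized (recorded in the run manifest, as
input files do not declare their scale).

## Instrument selection

The cascade applies, in a fixed order: association p < 1e-5 →
F = (β/se)² > 10 → cis window (gene interval ± 100 kb) → MAF ≥ 0.01 →
user exclusion list → palindrome removal → greedy LD clumping (sort by
ascending p; keep a SNP iff r² < 0.3 with every kept SNP within 100 kb,
ties broken by chromosome, position, then rsID). The order is a package
choice — clumping last retains the strongest independent signals; the
cascade's thresholds are the conventional drug-target MR settings and
are all configurable. Every removal is logged with a machine-readable
reason, and the identity |input SNPs| = |harmonized rows| + |exclusion
log| holds for every run.

Design choices worth noting:

- Palindromic (A/T, C/G) SNPs are dropped outright; no allele-frequency
  strand inference is attempted.
- SNPs lacking an allele frequency pass the MAF filter with a warning
  unless `strict_maf` is set; no frequency is ever imputed.
- Confounder screening is modelled as a user-supplied rsID exclusion
  list; the package performs no web lookups.
- LD is consumed as a precomputed pairwise r² table (absent pairs are
  unlinked); there is no genotype-panel handling.
- The cis rule takes the gene interval as input — gene coordinates are
  never hard-coded.

## Estimators and numerical conventions

- **IVW** equals the closed-form weighted least-squares solution of
  β̂Y = β·β̂X with weights seY⁻² (verified against the normal equations
  to 1e-10 in the tests). The random-effects variant uses
  multiplicative overdispersion floored at 1 — no underdispersion
  credit — so FE and RE coincide when Q ≤ L−1. IVW/Wald/median/mode
  p-values use the normal; Egger uses t(L−2). This mixed convention
  matches the software ecosystem this workflow comes from.
- **MR-Egger** orients rows so β̂Xj ≥ 0 before fitting (ratio estimates
  are invariant; the intercept is only identified in a fixed
  orientation) and scales both SEs by max(1, √(Q_resid/(L−2))).
- **Weighted median**: ratio estimates weighted by β̂X²/seY², sorted,
  with linear interpolation of the cumulative-midpoint weights at 0.5.
  SE = sd of 1,000 parametric-bootstrap replicates (β̂X*, β̂Y* drawn
  from their estimation normals, weights recomputed per replicate).
- **Modes**: Gaussian KDE over ratios with the modified Silverman
  bandwidth h = φ·0.9·min(sd, IQR/1.349)·L^(−1/5) (φ = 1 by default);
  argmax on a fixed 1,000-point grid spanning the ratio range ± 3h;
  if one spread measure is zero the other is used, and if all ratios
  coincide that ratio is returned. SE = 1.4826 × MAD of bootstrap
  replicates (robust to the mode's discreteness on the grid).
- **Method battery**: 1 instrument → Wald ratio; 2 → IVW; ≥ 3 → Egger,
  weighted median, IVW, simple mode, weighted mode, in that order.
- **MR-PRESSO**: expected outcome effects use leave-one-out
  *fixed-effect* IVW slopes (the original algorithm's choice); Monte
  Carlo p-values use add-one smoothing (1+count)/(n_sim+1) so they are
  never zero; per-SNP p-values are Bonferroni-multiplied by L; the
  distortion test is implemented but off by default. n_sim defaults to
  1,000. Results are bit-reproducible given (seed, n_sim).
- **Heterogeneity**: I² = max(0, (Q−df)/Q)·100 is the Q-based
  statistic, labelled `q_i2` in outputs to distinguish it from the
  I²GX instrument-strength metric (not implemented).
- **Mediation**: mediated = β1β2 with delta-method variance
  β1²se2² + β2²se1²; direct = total − mediated (exact by construction);
  proportion = 100·mediated/total with delta variance
  (100/total)²·var(mediated) + (100·mediated/total²)²·var(total) and a
  normal interval. All cross-covariances are set to zero: β1, β2 and
  the total come from two-sample contrasts on distinct instrument
  sets. This is approximate — the outcome GWAS is shared between step 2
  and the total effect — and the delta interval is first-order: it is
  accurate when the total effect is estimated precisely, and ignores
  the skew of the ratio when it is not (the tests validate it against a
  Monte-Carlo percentile oracle in the precise-total regime). β2 is
  the univariable step-2 IVW by default; computing β2 from an MVMR
  conditioning on the exposure is available by passing that estimate
  instead — with noisy real tables the two variants differ, and
  published mediation tables do not always state which entered the
  product.
- **MVMR**: weighted multiple regression without intercept; SEs carry
  overdispersion floored at 1 with L−k residual degrees of freedom.
  An exposure column that is identically zero is excluded from the fit
  and reported as a null conditional effect rather than raising a
  singularity error; genuinely collinear designs do raise.
- **Screening across mediators** applies a per-test α = 0.05 by
  default (no multiplicity correction — the convention in this
  workflow); Bonferroni and Benjamini–Hochberg are available and
  clearly opt-in.

Confidence level defaults to 0.95 everywhere.

## The simulator

`SimScenario` generates the three-cornered study at the summary level.
Per SNP: eaf ~ Uniform(0.05, 0.5); quantitative-trait SE =
1/√(2·n·eaf(1−eaf)); binary-outcome SE = √(1/(n·v·2·eaf(1−eaf))) with
case fraction v. True effects follow the path model

    exposure_j = γj            (cis instruments; 0 for null SNPs)
    mediator_j = β1·γj + αM,j + δj
    outcome_j  = βdirect·γj + β2·mediator_j + αY,j

where δj are mediator-specific instruments at a second locus (they give
the mediator its own valid instrument set for step 2) and αM/αY are
optional pleiotropic effects on a fraction π of instrument blocks.
Directional pleiotropy is drawn relative to the exposure-raising allele
(aligned with sign(γ)), which is the orientation in which the Egger
intercept is defined. LD is generated as blocks whose members share the
true effect and whose sampling noise is correlated at √r² — enough to
exercise clumping without genotype data — and the emitted LD table
reports the block structure. Observed betas add N(0, se²) noise;
palindromic allele pairs and randomly swapped allele order in the
non-exposure tables exercise harmonization.

Default calibration (the conditions under which all replicated tests
run): 30 instruments plus 200 null cis SNPs; exposure GWAS n = 31,684;
outcome GWAS n = 317,252 with case fraction 0.001 — the outcome is a
rare disease, and this case fraction puts the total-effect log-OR SE
near 0.29, the precision regime of a rare-disease GWAS of this size;
mediator GWAS n = 118,000 (a typical large metabolite panel; not tied
to a specific source); true ORs 0.917 (exposure→mediator), 2.0499
(mediator→outcome) and 0.4957 (total), so βdirect = ln 0.4957 −
ln 0.917·ln 2.0499 and the true proportion mediated is
100·β1β2/total ≈ 8.86%. Instrument strengths |γ| ~ N(0.06, 0.015) give
mean F ≈ 45 on the exposure; mediator instruments |δ| ~ N(0.05, 0.01)
give step-2 interval widths comparable to the step-2 total. The
directional-pleiotropy power scenario used in the tests sets π = 1,
μα = 0.1, σα = 0.05 — the magnitude at which the Egger intercept test
has roughly 50% power at L = 30 in this SE regime, so power is clearly
separated from the type-I level.

What the simulator does **not** emulate: real LD decay (block-constant
r² only), allele-frequency–dependent effect sizes, sample overlap
between GWASs, population stratification, winner's curse in instrument
discovery, and binary-trait non-collapsibility (outcome betas are drawn
directly on the log-odds scale). Passing calibration tests therefore
demonstrates the estimators' frequentist behaviour under the stated
generative model, not robustness to these real-data complications.

## Problem sizes in the replicated checks

Calibration studies use the fast pre-harmonized simulation path:
500 replicates for IVW coverage and null type-I error, 300 for
mediation-CI coverage, 200 datasets for the MR-PRESSO null rejection
rate (n_sim = 1,000 each), 200 for Egger power. These sizes give
Monte-Carlo SEs of about 1–3 percentage points on the rates being
checked, which is adequate for the ±3-point acceptance bands. The
acceptance script uses 300/300/100 replicates for its summary rates.

## Known limitations

- Wald-ratio and ratio-based SEs are first-order only.
- The delta interval for the proportion mediated can undercover when
  the total effect is weakly identified (|total|/SE ≲ 3); the
  simulator's default regime sits near that boundary, and the
  replicated coverage check (≥ 90% observed) quantifies the effect.
- MR-PRESSO's global test is a Monte-Carlo test; its resolution is
  bounded by 1/(n_sim+1).
- No Steiger directionality filtering, no MR-RAPS/contamination-mixture
  estimators, no GWAS-VCF input, no reference-panel LD computation.
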