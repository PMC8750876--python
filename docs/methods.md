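# Methods

`cytomr` implements a cis-instrument two-sample Mendelian randomization (MR)
pipeline relating genetically proxied circulating cytokine concentrations to
cancer risk, together with the sensitivity, multiplicity and colocalization
machinery such an analysis needs, and a synthetic-data generator that makes
every stage testable against known truth. This note records the model, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic experiments do and do not establish.

## The causal model and its assumptions

Each analysis treats germline variants near a cytokine's coding gene as
instruments for its circulating concentration X (measured in SD units) and
asks for the effect θ on a binary cancer outcome Y (log odds ratio per SD).
With per-variant summary estimates (β_Xj, se_Xj) and (β_Yj, se_Yj) from
non-overlapping samples, each instrument supplies a ratio estimate
θ̂_j = β_Yj / β_Xj whose first-order standard error is se_Yj / |β_Xj|. The
instruments must be (i) strongly associated with the cytokine, (ii)
independent of confounders, and (iii) affect cancer only through the cytokine.
Restricting to the cis region (gene ± 500 kb) addresses (iii) by design; the
estimator suite probes the residual violations.

## Instrument selection

* **cis-pQTL definition**: variants inside the gene ± 500 kb window (hg19,
  1-based) with MAF ≥ 0.05 and cytokine association p < 1e-4.
* **cis-eQTL definition**: window and MAF as above, requiring expression
  association p < 1e-4 (aggregated across tissues, taken as given in the
  expression input) *and* cytokine p < 0.05; effect sizes are always the
  cytokine estimates.
* **Clumping**: greedy on ascending p (ties: position, then variant ID), a
  candidate is accepted iff its LD r² with every accepted variant is < 0.1.
  The output is deterministic regardless of input order and always contains
  the smallest p-value.
* **Diagnostics**: per-variant explained variance r² = 2·eaf·(1−eaf)·β² for a
  unit-variance phenotype with β per SD; clumped variants are treated as
  independent when summing (their pairwise r² is below 0.1 by construction).
  F = r²(n−2)/(1−r²) per variant; per-cytokine F is the unweighted mean.
  Power for an OR of 1.2 per SD uses the two-sample binary-outcome normal
  approximation Φ(√(n·r²·φ(1−φ))·|ln OR| − z_{0.975}) with case fraction φ.

Cross-cohort pooling of SNP–cytokine estimates (Finnish GWAS with SCALLOP or
INTERVAL) is inverse-variance fixed-effect, gated on the Pearson correlation
of harmonized betas over shared variants (threshold 0.5 by default — the
criterion "correlates well" is inherently a judgment call, so the threshold
is a config knob). Cochran's Q across cohorts is reported but does not
inflate SEs at this stage: the cohorts measure the same trait, and
between-cohort spread is absorbed later by the random-effects MR model.

## Harmonization

Outcome effects are aligned to the exposure effect allele: matching pairs are
kept, swapped orientations flip the outcome beta, mismatched allele pairs are
dropped. Palindromic (A/T, C/G) variants are resolved by allele frequency
only when both EAFs are present and both minor-allele frequencies are below
0.42; otherwise they are dropped as ambiguous. The 0.42 limit is the common
practice bound — near 0.5 the frequencies cannot distinguish strands — and is
configurable. Every action is recorded in a per-variant provenance log, and
harmonization is an involution under allele swaps (tested).

## Estimators

All weights are first-order (w_j = β_Xj²/se_Yj²); second-order corrections
are deliberately not applied anywhere so that every method sees the same
weighting.

* **Wald ratio** for single-instrument cytokines; CI = θ ± 1.96·se.
* **IVW**, fixed or multiplicative random effects. The random-effects SE
  multiplies the fixed SE by max(1, √(Q/(J−1))); it can never undercut the
  fixed-effect SE. This floor makes the test conservative under exact
  homogeneity at small J (measured level ≈ 0.033 at J = 10), which is why the
  calibration experiment for the *nominal level* uses the fixed-effect
  variant (measured ≈ 0.05) and separately asserts the random-effects variant
  is never less conservative. Coverage experiments use the random-effects
  variant, the pipeline's primary estimator.
* **LD-aware IVW**: generalized regression through the origin with outcome
  covariance Ω_jk = se_Yj·se_Yk·r_jk; used to re-estimate FDR-significant
  pairs, since clumped instruments retain |r| up to ~0.3.
* **MR-Egger**: weighted regression with intercept after orienting all
  β_X ≥ 0; the intercept estimates directional pleiotropy. SEs carry the
  multiplicative inflation max(1, √(RSS_w/(J−2))).
* **Weighted median**: ordered ratios at cumulative midpoint weight 0.5 with
  linear interpolation; SE from a seeded parametric bootstrap (default 1000
  resamples of both betas from their reported SEs).
* **Contamination mixture (ConMix)**: each ratio is modeled as valid
  (normal around θ with its first-order SE) or invalid (normal around zero
  with variance inflated by ψ²); the profile log-likelihood over a 500-point
  grid spanning 3× the ratio range is maximized, with the 95% CI the region
  within 1.92 units of the maximum. Default ψ = 1.5 × SD of the ratio
  estimates. Disjoint CI regions are flagged multimodal and bracketed; a ψ
  far beyond the ratio spread is flagged uninformative (at very large ψ the
  invalid density vanishes, so the mixture cannot separate components).
* **MR-PRESSO**: the observed residual sum of squares from leave-one-out IVW
  predictions (residuals weighted by 1/se_Y²) is compared with its parametric
  null distribution (default 1000 simulations); per-SNP outlier p-values are
  Bonferroni-corrected over J, and the corrected estimate is the IVW on
  non-outliers. Empirical p-values use add-one smoothing, so the smallest
  attainable p is 1/(n_sim+1).
* **Multivariable MR**: weighted least squares of β_Y on all K exposure
  columns jointly, no intercept, df J−K inflation; rank deficiency is an
  error naming the collinear columns.

Applicability gates are explicit: Egger/median/ConMix need ≥ 3 instruments,
PRESSO ≥ 4; the pipeline records skips with their reason rather than hiding
them, because cis instrument sets are small by construction and these methods
are designed for polygenic settings.

## Multiplicity

Benjamini–Hochberg q-values per instrument definition (the two definitions
form separate test families by default; configurable to a pooled family);
q ≤ 0.10 is significant, boundary inclusive. The implementation is the exact
step-up min-cascade, tested against a brute-force definition on all small
grids and against an independent library implementation.

## Colocalization

For each FDR-significant pair, the region 25 kb on each side of the lead
cytokine variant (smallest p; ties to the smaller position) is tested under
the standard five-hypothesis single-causal-variant enumeration over Wakefield
log approximate Bayes factors, log ABF = ½ln(se²/(se²+W)) + z²W/(2(se²+W)).
Default priors are the widely used p1 = p2 = 1e-4 and p12 = 1e-5; prior
effect variances default to W = 0.2² for quantitative traits and 0.15² for
binary log-OR traits. All sums are log-sum-exp; the two-distinct-variants
term is S1·S2 − S12 over per-SNP ABF sums. A shared posterior strictly
greater than 0.8 is called colocalized, and the result notes whether the lead
variant falls inside the gene body. The single-causal assumption matters in
practice: regions simulated with several shared causal variants split
posterior mass between the shared and distinct hypotheses, which is why the
planted-signal demonstration uses a single causal variant.

## Synthetic data

`simulate_two_sample_region` draws an AR(1) LD correlation (r_jk = ρ^|j−k|,
default ρ = 0.8 — simple, positive definite, and strong enough to exercise
clumping and LD-aware estimation), EAFs uniform on [0.05, 0.95], and
`n_causal_exposure` standardized causal effects of fixed explained variance
(default 1% each, echoing the per-cytokine instrument strength of the study
panel, e.g. five variants summing to ~5%). Marginal effects are the LD
propagation of the causal vector; sampling noise is multivariate normal with
the LD correlation and per-variant SEs 1/√(2p(1−p)n) for the quantitative
exposure and 1/√(2p(1−p)·n·φ(1−φ)) for the case-control outcome. Pleiotropy
is per-variant: none, balanced (zero-mean normal) or directional
(half-normal), added to the marginal outcome effects. Defaults mirror the
study scale: exposure n = 13,365; outcome n = 85,716 with φ = 0.3415 (the
lung GWAS); the two samples are independent.

`simulate_catalog` writes a complete input bundle (region table, per-cytokine
exposure/expression/LD files, per-outcome files, truth manifest) whose layout
the pipeline consumes unchanged; a cytokine's genetics and exposure GWAS are
drawn once and shared across outcomes, and an `outcome_salt` redraws only the
outcome noise — the construction used for replication experiments.

What the generator does *not* emulate: sample overlap between exposure and
outcome GWAS, winner's curse in instrument discovery, strand errors or allele
ambiguity beyond the palindromic rule, block-structured LD, and trans
pleiotropy networks across cytokines. Passing calibration on this generator
therefore shows the estimators and pipeline are correct under the stated
model, not that real-data biases of those excluded kinds are handled.

## Problem sizes and seeds

Calibration experiments use 2000 replicates (IVW level and coverage, FDR
null), 200 replicates (robust-estimator recovery, coloc recovery, full-path
effect recovery) and 100 seeded runs (PRESSO), with J = 10 instruments and
strong-instrument SEs (exposure SE 0.02 on effects ~0.15, outcome SE 0.03) —
sizes chosen so every experiment has Monte-Carlo error well below the
tolerances it checks while the whole suite runs in minutes on one CPU. All
randomness derives from a single seed through SHA-256 per-task derivation
(`derive_seed`), so partial re-runs are stable and every result is
bit-reproducible given the seed.

## Reproducing the published numbers

The package ships the study's per-cytokine gene-region and instrument-strength
catalog (`src/cytomr/data/cytokine_gene_regions.tsv`; hg19 coordinates).
Recomputing medians over it reproduces the published instrument summaries:
31 cytokines with cis-pQTL instruments (median 5 per cytokine, median summed
r² 1.60%, IQR 0.55–6.65%) and 27 with cis-eQTL instruments (median 2, r²
≈ 0.5%). The headline odds ratios (e.g. IL-18 → lung 0.87, 0.81–0.93; RANTES
→ serous ovarian 0.70, 0.57–0.85) require the study's per-SNP supplementary
association tables, which are not redistributable here; when a user supplies
them as canonical TSVs under `data/external/` the pipeline recomputes the
full 1013-test grid and the acceptance test checks every headline OR to two
decimals. Without them, the corresponding test fails explicitly rather than
passing vacuously, and the statistical property suite plus the lung-scale
recovery experiment (mean recovered OR ≈ 0.873 against a truth of 0.870)
stand in as the computable evidence.

## Known limitations

* Expression aggregation across tissues is consumed, not performed; the
  eQTL definition trusts the supplied expression p-values.
* Total instrument r² sums per-variant r² over clumped variants; a joint
  model would be slightly smaller under residual LD.
* ConMix CIs come from a fixed grid; resolution is span/500.
* The coloc module is single-causal-variant; no SuSiE-style extension.
* Wald/IVW first-order SEs ignore exposure-side noise; with mean F well
  above 10 (the study's regime) the bias is negligible, and weak-instrument
  settings are outside scope.
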