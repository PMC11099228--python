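# Methods

## Model and assumptions

All estimation operates on two-sample GWAS summary statistics. For each
instrument SNP *j* the data are the estimated association with the exposure
(γ̂ⱼ, se γⱼ) and with the outcome (Γ̂ⱼ, se Γⱼ), assumed Gaussian,
independent across SNPs (instruments are approximately LD-independent after
clumping) and between samples (no cohort overlap). A variant is a valid
instrument if it is (1) associated with the exposure, (2) affects the
outcome only through the exposure, and (3) is independent of confounders.
Binary outcomes are treated on the log-odds scale throughout; odds ratios
are exp(β).

## Instrument selection

The cascade, in order: p-value threshold on the exposure (default 1e-5;
5e-8 when a disease outcome is analysed as exposure in the reverse
direction) → greedy LD clumping → exclusion of SNPs associated with the
outcome at p < 5e-5 (SNPs absent from the outcome table are dropped as
unmatched, counted separately) → allele harmonization with unconditional
removal of palindromic (A/T, C/G) SNPs → strength and frequency filter:
per-SNP F = (β̂/se)² strictly greater than 10 and MAF = min(eaf, 1−eaf)
≥ 0.01. The F formula is the squared Wald z, the standard summary-data
approximation; the strictness of "greater than 10" is deliberate.

Clumping is greedy by ascending p-value (ties broken by SNP id so results
are deterministic): a SNP is accepted iff its r² with every
already-accepted SNP on the same chromosome within the window (default
10,000 kb) is below the threshold (default 0.001). LD comes from a
user-supplied labelled r² matrix; pairs absent from it are treated as
independent and logged. This replaces reference-panel clumping with an
explicit, testable input and keeps the greedy semantics.

Harmonization aligns the outcome record to the exposure's effect allele:
identical alleles copy, swapped alleles negate the outcome beta (and
complement the frequency), strand flips are resolved by base-complementing
before applying the same rule, and irreconcilable pairs are dropped with a
log entry. Palindromic SNPs are never rescued by allele frequency.

## Univariable estimators

- **IVW**: zero-intercept weighted regression of Γ̂ on γ̂, weights 1/se Γ².
  The default is multiplicative random effects: the fixed-effect SE is
  inflated by max(1, √(Q/(k−1))), which equals the fixed model when the
  heterogeneity statistic Q is small. p-values use the normal reference.
- **MR-Egger**: the same regression with a free intercept, after orienting
  all γ̂ non-negative (the intercept is only identified up to this
  convention). Slope and intercept SEs carry the same multiplicative
  overdispersion floor max(1, σ̂); p-values use t with k−2 df. The
  intercept estimates directional pleiotropy under InSIDE.
- **Weighted median**: Wald ratios ordered ascending with normalized
  inverse-variance weights (ratio variance by the first-order delta
  approximation se Γⱼ²/γ̂ⱼ²); the estimate interpolates the ratio at
  cumulative weight 0.5 on the grid sⱼ = Σᵢ≤ⱼ wᵢ − wⱼ/2. SE by seeded
  parametric bootstrap (default 1,000 resamples of (γ̂, Γ̂) from their
  sampling normals), so SEs are bit-reproducible given a seed.
- **Weighted / simple mode**: argmax of a (weighted) Gaussian KDE of the
  Wald ratios, bandwidth 0.9·min(sd, mad)·k^(−1/5) times a user factor
  (mad normal-consistent). If the ratios are all equal the common value is
  returned directly. The "simple" variant uses uniform weights. SE by the
  same bootstrap.
- **Wald ratio**: the single-instrument case, β̂ = Γ̂/γ̂ with first-order
  SE se Γ/|γ̂| (the second-order term is omitted, documented here).

All estimators are equivariant under joint per-SNP sign flips, so the
harmonization orientation cannot change an estimate, and all return c
exactly when every Wald ratio equals c.

## Multivariable IVW

Weighted least squares of Γ̂ on the k×m matrix of exposure effects, no
intercept, weights 1/se Γ², requiring full column rank and k ≥ m+1
instruments. Per-coefficient SEs carry the overdispersion floor
max(1, σ̂); p-values use t with k−m df. With m = 1 this reproduces the
univariable IVW beta and SE exactly. Instrument assembly takes the union of
per-exposure instruments (threshold + strength/frequency filter per
exposure), jointly clumps the union using each SNP's best p-value, aligns
all datasets to the first exposure's effect allele, and drops SNPs missing
from any table. Union rather than intersection preserves instrument
strength for every exposure; re-clumping the union guards against
cross-exposure LD.

## Sensitivity battery

- **Cochran's Q** over Wald ratios around the IVW estimate, weights
  γ̂ⱼ²/se Γⱼ², χ² with k−1 df.
- **Egger intercept test**: intercept and its t-based p from the Egger fit.
- **MR-PRESSO**: observed RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₋ⱼγ̂ⱼ)² with β̂₋ⱼ the
  leave-one-out IVW slope; the null distribution comes from parametric
  simulations Γ̂*ⱼ ~ N(β̂₋ⱼγ̂ⱼ, se Γⱼ), γ̂*ⱼ ~ N(γ̂ⱼ, se γⱼ) with the
  leave-one-out slopes recomputed inside each simulation (defaults:
  1,000 simulations; the empirical global p is reported as "< 1/n_sim"
  when no simulated RSS reaches the observed one). Per-SNP residual
  p-values are Bonferroni-adjusted across instruments and compared to 0.05
  for outlier flagging; when outliers exist, an outlier-removed IVW refit
  and a distortion p (resampling the outlier slots from the non-outlier
  ratios, 1,000 draws) are reported. Everything is seeded and
  bit-reproducible.
- **Leave-one-out**: k IVW refits, one per omitted SNP, in input order.

Decision rules: heterogeneity is flagged when the Q p-value is below 0.05;
pleiotropy is flagged when the Egger-intercept p or the PRESSO global p is
below 0.05, and a flagged pair's causal claim is marked invalidated in the
pipeline output (pleiotropy invalidates the exclusion-restriction
assumption).

## Mediation screen

For every exposure–outcome pair with a significant total effect β, each
candidate mediator passes through the four steps listed in the README. The
screening fits for steps 1 and 2 apply the Egger-intercept gate (a fit with
intercept p < 0.05 is excluded as pleiotropic). The reported mediation
p-value is the multivariable p of β₂; a delta-method p for the product
β₁β₂ (variance β₂²·se β₁² + β₁²·se β₂²) is additionally available as an
extension, clearly separated. The proportion CI rescales the delta-method
CI of the product by β. Candidates whose proportion falls outside [0, 1]
are retained but flagged "inconsistent mediation" rather than silently
dropped. BH-FDR q-values are computed per outcome family by default (the
family key is configurable to "all") via the standard step-up procedure.

A fixture-injection mode applies the step-4 retention rule to a table of
precomputed candidate estimates, so the decision logic can be exercised —
and the bundled 20-row example table reproduced (7 retained pathways,
6 distinct mediator phenotypes) — without any per-variant data.

## Synthetic generator

Each study is a shared panel of independent SNPs observed in three tables.
True effects: exposure instruments γⱼ ~ N(0, effect_sd²); mediator
instruments δⱼ ~ N(0, mediator_effect_sd²) (defaults to effect_sd);
mediator truth β₁γⱼ + δⱼ; outcome truth (direct + β₁β₂)γⱼ + β₂δⱼ + a
pleiotropy term (balanced: mean-zero, drawn independently of γ so InSIDE
holds; directional: constant mean). Observed betas add N(0, seⱼ²) with
seⱼ = 1/√(2·n·eafⱼ(1−eafⱼ)); p-values are two-sided normal. Binary
outcomes are simulated directly on the log-odds scale — two-sample MR
consumes only summary statistics, so individual-level logistic sampling
would add cost without changing what the estimators see. Decoy SNPs
(palindromic allele pairs; sub-1%-MAF variants) carrying real signal are
injected at configurable rates to exercise the harmonization and frequency
filters. LD is not simulated; a block-diagonal LD injector exists solely to
test the clumper. Default sample sizes (7,738 / 3,757 / 24,108) mirror a
cohort-scale microbiome GWAS, a flow-cytometry immune-phenotype GWAS and a
case-control lung-cancer GWAS; with the default effect scale, the 1e-5
selection threshold implies F ≳ 19.5 for every retained instrument, i.e.
the strong-instrument (F > 15) regime. Instrument counts from a handful up
to >200 are reachable through n_snp and effect_sd (see the test suite).

What the generator does **not** emulate: realistic allele-frequency
spectra, LD between instruments, population stratification, sample overlap
between the exposure and outcome GWAS, and case-control asymmetries in the
SE formula. Passing tests therefore validate the estimators and the
decision logic under the stated sampling model, not robustness to those
real-data complications.

## Validation experiments and their problem sizes

`axismr.experiments` fixes the conditions shared by the test suite and the
acceptance script:

- **Parameter recovery** (β₁ = 0.5, β₂ = 0.2, direct 0.2; truth: total
  0.3, proportion 1/3): 100 true instruments per trait, 200 seeded
  replicates, medians reported. The instrument-side GWAS is large
  (n = 400,000, per-instrument F in the hundreds) so selection-induced
  winner's curse is negligible, and the downstream GWAS are sized
  (n = 13,000 mediator, 20,000 outcome, effects 0.03/0.15, EAF 0.2–0.5)
  so that true propagated per-SNP effects stay below the 5e-5
  outcome-association exclusion threshold. This matches the regime of the
  studies the generator emulates, where that filter removes almost
  nothing; if instead downstream GWAS are made arbitrarily precise, the
  filter preferentially deletes the strongest true instruments and
  attenuates every estimate — a real property of the protocol worth
  knowing, not a software artifact.
- **Null calibration**: 2,000 null-study replicates at ~110 retained
  instruments. The overdispersion floor max(1, σ̂) makes the IVW and
  Egger-intercept tests conservative at small k (analytically, rejection
  ≈ 0.02 at k ≈ 17 but ≈ 0.04 at k ≈ 100), so the nominal-level check is
  run at the upper, immune-cell-like end of the instrument-count range
  where the finite-sample distortion is negligible.
- **Outlier power**: ~20 instruments with one outcome effect displaced by
  10 outcome-SEs, 200 replicates, 1,000 PRESSO simulations each.

## Numerical choices

- 95% CIs use z = 1.959964; Egger and multivariable p-values use t
  distributions with k−2 and k−m df respectively.
- Clumping ties are broken by SNP id (stable sort), making the whole
  cascade byte-deterministic.
- The KDE mode is evaluated on a 2,001-point grid spanning the ratio range
  ± 3 bandwidths; degenerate spreads short-circuit to the common ratio.
- Bootstrap and simulation SEs use numpy's PCG64 generator with explicit
  seeds; replicate seeds are spawned from a master seed and kept below
  2³¹.
- p-values are clipped into (0, 1]; the generator floors simulated
  p-values at the smallest positive double.
- Zero exposure effects make a Wald ratio undefined and raise an
  estimation error; a zero total effect makes the mediation proportion
  undefined and raises a screening error.

## Design choices on genuinely open points

- "Sample mode" among the five supplementary estimators is read as the
  simple (unweighted) mode estimator — the standard five-method battery;
  noted rather than silently corrected.
- The IVW default is multiplicative random effects; the fixed model is one
  keyword away.
- The outcome-association exclusion is applied after clumping and before
  harmonization; unmatched and excluded SNPs are counted separately.
- Multivariable instrument assembly uses the union of per-exposure
  instruments with joint re-clumping (see above).
- The mediation p is the multivariable p of β₂; whether a dedicated
  uncertainty for β₁β₂ should gate retention is left as the clearly
  labelled delta-method extension.
- A genus and its single species with identical estimates count as
  distinct pathways in the bundled candidate table, mirroring how such
  ties are reported in practice.

## Known limitations

- At realistic cohort scales the pipeline inherits the usual two-sample MR
  biases (winner's curse from same-sample instrument selection, weak-
  instrument attenuation); the recovery experiment deliberately works in a
  regime where these are negligible, so it validates correctness of the
  implementation, not unbiasedness of the protocol at any scale.
- Proxy-SNP lookup, Steiger directionality filtering, radial MR,
  MVMR-Egger and conditional F-statistics are out of scope.
- Reverse-direction screening declares a pair reverse-causal when both
  directions are significant at 0.05; no effect-size comparison is
  attempted.
- The distortion test is reported only when outliers exist, and its
  resampling scheme (outlier slots refilled from non-outlier ratios)
  follows the published algorithm's spirit but is not a formal test of
  estimator shift.
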