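# Methods

## Estimand and assumptions

The package estimates θ, the log odds ratio of a binary outcome per unit
(SD) of a quantitative exposure, from two independent GWAS: one reporting
per-allele variant–exposure effects β̂_ZX with standard errors SE_ZX, one
reporting per-allele variant–outcome log-ORs β̂_ZY with SE_ZY. Validity of a
variant as an instrument requires (i) robust association with the exposure,
(ii) independence from confounders of the exposure–outcome relation, and
(iii) no effect on the outcome except through the exposure. (i) is enforced
by the selection screens; (ii) is the Mendelian-inheritance argument and is
untestable from summary data; (iii) is probed by the MR-Egger intercept.

## Wald ratio and its standard error

Per variant, β̂_XY = β̂_ZY / β̂_ZX. The default SE is the first-order delta
method, SE_XY = SE_ZY / |β̂_ZX|, which treats the exposure effect as fixed.
The second-order term (β̂_ZY² SE_ZX² / β̂_ZX⁴) is omitted by default: for
instruments passing the P < 5×10⁻⁸ screen it is an order of magnitude
smaller than the first-order term. An alternative `se_method="paper-literal"`
computes SE_ZY / SE_ZX; this formula circulates in some applied write-ups
but is dimensionally inconsistent (it does not scale with the instrument
strength) and is provided strictly for comparison — with the packaged
eight-SNP table it inflates the pooled CI by a factor of ~7.

## IVW pooling and model selection

Fixed-effect: β̂ = Σwᵢβ̂_XY,ᵢ / Σwᵢ, wᵢ = SE_XY,ᵢ⁻², SE = (Σwᵢ)^(−1/2).
Heterogeneity: Q = Σwᵢ(β̂_XY,ᵢ − β̂)², referred to χ²(k−1);
I² = max(0, (Q − (k−1))/Q) × 100, set to 0 when Q = 0 and capped at 100.
Random-effects uses the DerSimonian–Laird moment estimator
τ² = max(0, (Q − (k−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ)), re-weighting by
(SEᵢ² + τ²)⁻¹; with τ² = 0 it reproduces the fixed-effect result exactly.
Under `model="auto"` the random-effects model is used only when Q's p-value
is below 0.01 **and** I² exceeds 50% (both thresholds are arguments).
P-values are two-sided normal; all 95% intervals use the critical value
1.959964, which matches the printed precision of the reference analysis.
A Q-test p of 1.0 is reported as computed, without "<" clamping.

## Instrument selection

`filter_instruments` keeps variants with p_exposure < 5×10⁻⁸ (strict),
β_exposure ≠ 0 and p_outcome > 0.05 (strict). `ld_prune` implements greedy
pruning: variants ranked by ascending exposure p-value (ties broken by
variant_id for determinism); a variant is removed only when it lies within
500 kb of an already-kept variant on the same chromosome *and* has r² ≥ 0.1
with it. Distance alone never prunes — a pure distance rule would be unable
to retain the packaged table's seven chromosome-2 instruments spanning
< 700 kb, which were established as independent upstream. A missing r² for
an in-window pair is treated as above threshold (prune) by default;
`strict_missing_ld=False` treats it as 0. r² values come from a
user-supplied table; the package never computes LD from genotypes.

Harmonization aligns outcome effects to the exposure's effect allele,
negating β̂_ZY when the datasets report opposite alleles. Allele pairs that
are neither identical nor a strict swap are dropped with a logged reason (no
strand inference is attempted). Palindromic variants (A/T, C/G) are excluded
by default because strand cannot be resolved without allele frequencies.
When neither dataset carries allele labels the records are joined as-is —
the caller asserts pre-harmonization, which is the situation of the packaged
table (alleles not printed; outcome effects already oriented to the
IL-18-raising allele, the only orientation consistent with its published
pooled results).

## Leave-one-out and MR-Egger

Leave-one-out re-runs the IVW pool omitting each instrument in turn and
reports the relative OR fluctuation (OR_loo − OR_full)/OR_full. It requires
k ≥ 3 so every subset still supports pooling and heterogeneity assessment.

MR-Egger regresses β̂_ZY on β̂_ZX with weights SE_ZY⁻² and a free intercept,
after orienting every instrument to its exposure-increasing allele (the
intercept's sign is otherwise unidentified). The fit itself is ordinary
weighted least squares (statsmodels WLS); standard errors use multiplicative
overdispersion with the residual standard error floored at 1, so
underdispersion never shrinks SEs below the fixed-variance ones. P-values
and CIs use the normal distribution by default (`p_method="t"` switches to
t on k−2 df, which is more conservative at small k). The intercept estimates
the average directional pleiotropic effect; the slope is a
pleiotropy-adjusted causal estimate, consistent under InSIDE (instrument
strength independent of direct effects).

On the packaged eight-SNP table the Egger slope is exactly 0 and the
intercept 0.00995: the printed outcome effects are a single rounded value
shared by all eight variants, which forces a flat regression. Published
Egger coefficients for this dataset evidently derive from unrounded effects
that were never deposited, so the packaged table cannot reproduce them; the
Egger implementation is instead validated against a closed-form
weighted-normal-equations oracle on random instrument sets and against the
IVW identity (zero-intercept slope ≡ IVW estimate).

## Synthetic data generator

`simulate_two_sample` draws from the linear structural model under which
IVW and Egger are consistent: per variant, a true effect β_ZX with magnitude
uniform on [0.06, 0.10] (the packaged table's range; sign random unless
`positive_exposure`), a direct effect α ~ N(pleiotropy_mean, pleiotropy_sd²),
and observed effects β̂_ZX = β_ZX + N(0, SE_ZX²),
β̂_ZY = θβ_ZX + α + N(0, SE_ZY²) with independent noise (non-overlapping
samples). Default SEs mirror the packaged table: SE_ZX = 0.01, SE_ZY uniform
on [0.0102, 0.0153]. Instruments are generated mutually independent and
placed far apart, matching the post-LD-pruning assumption; the generator
does not emulate LD structure, allele-frequency-dependent power, winner's
curse in instrument discovery, or sample overlap — passing recovery tests
therefore validates the estimator arithmetic and its sampling theory, not
robustness to those real-data features.

`recovery_experiment` runs simulate → harmonize → Wald/IVW (and Egger at
k ≥ 3) per replicate and reports the Monte-Carlo mean/SD of the IVW
estimate, 95% CI coverage of θ, and the mean Egger intercept. Two design
choices: (1) the outcome-independence screen (p_outcome > 0.05) is *not*
applied inside replicates — it is a data-preparation step, and conditioning
on the outcome p-value truncates the sampling distribution being measured
(with θ = 0.13 it would discard ~17% of draws asymmetrically and bias the
Monte-Carlo mean toward zero); (2) pleiotropy-recovery runs generate
exposure effects on the exposure-raising orientation, because directional
pleiotropy is defined relative to that allele — with random signs, the
orientation step converts a directional α into a balanced one.

Intercept recovery is checked at θ = 0. With θ ≠ 0, exposure-side sampling
noise attenuates the Egger slope (the NOME violation: regression dilution
with I²_GX < 1) and the lost slope leaks into the intercept — a property of
the estimator, not of this implementation; at the default instrument
strength the leak is ≈ 0.005 per θ = 0.13.

Validation problem sizes: k = 50 instruments and 500 replicates for the
recovery experiments, 100+ random instrument sets for the Egger oracle
checks — large enough that Monte-Carlo error is a few percent of the
quantities asserted, small enough that the whole suite runs in seconds.

## Numerical and degenerate-input choices

- Strict inequalities throughout the screens (P < 5×10⁻⁸, P > 0.05).
- Wald ratio undefined at β̂_ZX = 0 → error (such variants are filtered).
- Egger with all exposure effects equal after orientation → singular-design
  error; k < 3 → error for Egger and leave-one-out.
- Simulated p-values are clipped to the smallest positive normal double so
  they remain in (0, 1].
- Reading: TSV/CSV auto-detected, `NA` or empty for missing; writing uses
  shortest round-tripping float representation, so write → parse is the
  identity at full precision.
- The packaged table stores printed values verbatim, including one position
  that is internally inconsistent in the source (flagged in provenance) and
  outcome p-values that are not reconcilable with the shared rounded
  beta/SE pairs; no reconciliation is attempted.

## Known limitations

Only Wald/IVW and MR-Egger estimators are provided (no weighted median,
mode, or outlier-removal methods); no Steiger directionality test; no
computation of LD from reference panels; binary-outcome effects are assumed
to be log-ORs on a consistent scale across variants. The auto model rule is
a threshold decision and inherits the usual discontinuity criticisms of
test-then-pool procedures.
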