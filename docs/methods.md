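# Methods

## The validation problem

A questionnaire scale is validated against categorical diagnoses by
asking how well its raw score separates diagnosed cases from controls
under three increasingly demanding contrasts: *sensitivity* (cases vs.
everyone else), *specificity* (cases vs. participants with only
non-depression diagnoses) and *strict specificity* (comorbidity-free
cases vs. the same controls). The package implements that design as a
library of small, separately testable stages plus a config-driven runner.

## Synthetic cohort model

No public dataset carries the multi-informant structure this analysis
needs, so the generator produces it from an explicit latent-liability
model:

1. Each participant has a true liability vector `L ~ N(0, R)` for
   depression, anxiety and ADHD, where `R` is a unit-diagonal PSD
   correlation matrix encoding comorbidity (defaults: dep-anx 0.45,
   dep-adhd 0.30, anx-adhd 0.30, in line with the strong observed
   co-occurrence of internalising and externalising disorders).
2. Informant `r` perceives disorder `d` as
   `P[r,d] = ρ_r L[d] + sqrt(1 − ρ_r²) ε`, ε standard normal. The
   fidelity ρ_r is the truth-perception correlation; defaults ρ_parent =
   0.9 and ρ_child = 0.3 are chosen so that parent-report agrees well
   with truth while child self-report agrees weakly — the regime that
   makes concordant parent/child positives the rarest cell of the
   agreement table, as seen in community cohorts.
3. Informant diagnosis of `d` is the liability-threshold rule
   `P[r,d] > Φ⁻¹(1 − prevalence_d)`. Default prevalences: depression
   0.05, anxiety 0.10, ADHD 0.10 — community-level rates.
4. The clinician consensus blends the informants,
   `C = w P_parent + (1 − w) P_child + σ_c η` with defaults w = 0.7 (most
   consensus procedures weigh parent material heavily for this age
   range) and σ_c = 0.3, and applies the same quantile threshold. The
   blend is deliberately *not* re-standardised: the threshold is the one
   implied by the nominal prevalence on the unit-variance scale, so the
   clinician's empirical diagnosis rate runs slightly below nominal
   (the blend's variance is below 1). This keeps step (4) a pure
   function of the stated quantities.
5. Ordinal items (three-point Likert, 0/1/2) follow a graded
   cumulative-logistic response model on the informant's perceived
   depression liability: `Pr(X_j ≥ k) = expit(a_j (P − b_jk))` with
   loadings a_j ∈ [1.2, 2.2] and mostly high thresholds, so raw scores
   pile up near zero as checklist scores do in the general population.
   One uniform draw per item keeps the cumulative categories nested.
   The default 13-item parameter set is fixed (drawn once from a frozen
   generator) and shipped as the reference configuration.

Sex is assigned 50/50 independently of liability (the analysis pools
sexes; a `group_by_sex` switch re-runs the grid per sex). Ages are
uniform integers in the configured range (default 8–12). Missingness is
emitted only as configurable completely-at-random rates on items and on
diagnosis flags, both 0 by default.

All randomness flows from one seed through named `SeedSequence`
substreams (liability, perception, clinician, items, demographics,
missingness — in spawn order), so each stage is reproducible in
isolation and adding a stage never perturbs earlier draws.

**What the generator does not emulate:** item content, instrument
differences between diagnostic interviews, longitudinal waves, informant
biases that vary with age or sex, non-random missingness, and the exact
cell counts of any real cohort's agreement table. Passing tests show the
pipeline is correct and the qualitative informant structure is
reproduced; they say nothing about any particular real dataset's
numbers.

## Scale scoring

Scores are raw item sums (no t-scores, no age/sex norming). The default
missing-item policy is `exclude` — any missing item makes the score
missing, matching the participant-omission rule of the validation
design. A `prorate` policy (round(mean(present) × n_items), half away
from zero, requiring ≥ 50% of items present) is offered as an extension
because checklist practice sometimes allows limited missingness; it is
off by default, and the 50% floor and rounding rule are package choices.

The default 13-item scale maps onto the simulator's items; on real data
the item membership of a scale is configuration (the authoritative item
lists live in restricted supplements, so the shipped default is a
placeholder in that sense).

## Contrasts and balancing

Diagnosis flags are abstract per-reporter booleans; which
instrument-specific codes map into "depression" / "anxiety" / "ADHD" /
"other" umbrellas is configuration upstream of this package. For strict
specificity, *any* non-depression flag disqualifies a case — the literal
reading of "without comorbidities". Before contrasts, the completeness
step retains exactly the participants with full diagnosis data for the
required reporters and a fully scorable scale, and an optional inclusive
integer age filter is applied.

Balancing keeps all cases and draws
`round(n_pos · (1 − r)/r)` controls (half-away-from-zero; at the default
r = 0.10 that is 9 × n_pos, e.g. 71 → 639, 30 → 270) uniformly without
replacement from the sorted control pool under a caller-supplied seed.
A short pool triggers the all-controls fallback and a `ratio_met=False`
marker. Whether the original analyses drew controls randomly or
deterministically is not documented anywhere; seeded uniform sampling is
this package's choice.

## AUCROC and bootstrap inference

The AUCROC is computed by the rank (Mann-Whitney) formula with the
half-credit tie convention — integer scale scores guarantee massive
ties, and half credit is the standard, symmetric choice that coincides
with the trapezoidal area under the tie-aware ROC (asserted to 1e-12 in
tests). The ROC itself is emitted with one point per distinct score
threshold plus the origin, classification rule `score ≥ t`.

Bootstrap: B resamples (default 1000), default scheme **stratified**
(cases and controls resampled separately, preserving class counts) —
with 30 cases in a 10% design, joint resampling produces single-class
resamples often enough to matter. The `simple` joint scheme is retained
behind a flag for sensitivity analysis; it skips-and-redraws
single-class resamples and reports the redraw count.

The one-sided p-value against the performance threshold (default 0.8)
for H0 "performance below threshold" is `#{AUC_b > 0.8} / (B + 1)` — the
+1 standing for the original arrangement of the data, giving the 1001
denominator at B = 1000. A zero count is reported as the floor
`<1/(B+1)` (rendered `<0.001` at B = 1000) with an explicit `at_floor`
marker rather than as zero: the count-based p can never be exactly 0.
The numerator deliberately does **not** add 1 for the original sample;
the denominator-only reading of the "+1" convention is implemented, with
the floor rule making the zero-count case honest. Two-sided p-values are
`min(1, 2·min(#{≤ t}, #{≥ t})/(B+1))` — twice the smaller tail share on
the same denominator, a package choice since only the fact of two-sided
reporting, not its formula, is conventionally stated. Confidence
intervals are percentile intervals with linear-interpolation quantiles
(NumPy's default), fixed for bit-reproducibility across equal-seed runs.

Calibration: at true AUC exactly 0.8 (binormal scores, separation
d = √2·Φ⁻¹(0.8) ≈ 1.1902, 50 cases / 450 controls) the one-sided test at
α = 0.05 rejects in roughly 4% of replicates; the test suite asserts the
[0.02, 0.09] band over 500 replicates at B = 500 — a loose band because
the percentile bootstrap is only approximately pivotal at these class
sizes. The suite runs this at those sizes (≈ 50 s) as its single heavy
check.

## Cutpoints

Candidate cutoffs are the midpoints between adjacent distinct scores
plus the two degenerate rules ±∞, which enumerate every achievable
confusion matrix exactly once. The default criterion is Youden's
J = sensitivity + specificity − 1 (the usual default when the selection
criterion is otherwise unspecified); closest-to-(0,1) is provided as an
alternative. Ties on the criterion break toward higher specificity
(fewer false positives — screening parsimony); when *every* candidate is
tied (an uninformative constant score) the degenerate all-positive
cutoff is returned with the tie flag set, so the caller sees both the
convention and the degeneracy. PPV/NPV are reported at sample
prevalence; empty denominators yield NaN.

## Agreement

Cross-informant tables are exact 2×2 counts after pairwise deletion of
missing ratings. Cohen's κ = (p_o − p_e)/(1 − p_e) returns NaN when
p_e = 1 (both raters constant). κ is symmetric under rater swap and the
table transposes accordingly.

## Pipeline

`run_validation` executes the grid (contrast × reporter × scale,
optionally × sex) deterministically: per-row balance and bootstrap seeds
are derived from the run seed and the row index via `SeedSequence`, and
every exclusion count and derived seed is written to a sidecar log, so
the sample flow of a run is reconstructible after the fact.
Unconstructible contrasts (e.g. no comorbidity-free cases) become NA
rows carrying the reason, so a multi-contrast run always completes.
Reports render with floats at 3 decimals and the `<` floor notation
preserved; equal config and seed give byte-identical report files.

## Known limitations

- The generator's defaults are calibrated to the *qualitative*
  informant-discordance pattern, not fitted to any real cohort's counts.
- The clinician consensus is a linear blend with Gaussian noise; real
  consensus procedures are discrete and adversarial.
- The percentile bootstrap's coverage at 30 cases is approximate; no
  DeLong variance estimation or correlated-AUC comparison is provided.
- Scales are scored for a single reporter at a time; cross-reporter
  composite scores are out of scope.
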