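# screenval

Diagnostic validation of ordinal questionnaire scales against categorical
psychiatric diagnoses, built for the multi-informant setting of child and
adolescent mental-health cohorts: a parent fills in a checklist, the child
answers a self-report interview, and (in some cohorts) a clinician team
issues a consensus diagnosis. The central question the package answers is
whether a raw scale score — say a 13-item DSM-oriented depression scale
scored 0/1/2 per item — discriminates diagnosed from undiagnosed
participants, and whether it does so *specifically* for the target disorder
rather than for psychopathology in general.

Because the cohorts this kind of analysis is usually run on (ABCD, HBN,
BHRC) are access-restricted, the package ships a first-class synthetic
cohort generator with the statistical structure those cohorts exhibit —
low disorder prevalences, depression/anxiety/ADHD comorbidity, strong
parent-clinician concordance and weak parent-child concordance — so the
entire pipeline is testable end-to-end without restricted data.

## What it computes

For each contrast × diagnosis reporter × scale:

- **Sensitivity contrast** — cases = participants with a depression
  diagnosis, controls = everyone else (healthy included).
- **Specificity contrast** — the same cases (comorbidity allowed),
  controls = participants with at least one non-depression diagnosis and
  no depression.
- **Strict specificity contrast** — cases restricted to depression with
  no comorbid flag, same controls as specificity.

Controls are subsampled (seeded, uniform, without replacement) so that
cases form 10% of the analysis sample; when too few controls exist, all
are kept and a ratio-not-met marker is set.

Discrimination is the AUCROC with the tie-aware Mann-Whitney convention,

AUC = P(S⁺ > S⁻) + ½ P(S⁺ = S⁻),

with inference by case/control-stratified bootstrap: the AUCROC is
recomputed on each of B = 1000 resamples and the one-sided p-value
against a fixed performance threshold (0.8, "excellent") is
`#{AUC_b > 0.8} / (B + 1)`; a zero count is reported as the floor
`<0.001`. Two-sided p-values double the smaller tail share; confidence
intervals are 95% percentile intervals. The package also reports
Youden-optimal cutoffs with confusion matrices, Pearson correlations
between scales, and cross-informant 2×2 agreement tables with Cohen's κ.

## Worked example

Simulate a 6000-participant cohort with the default generator (5%
depression prevalence, parent fidelity ρ = 0.9, child fidelity ρ = 0.3,
clinician consensus weighted 0.7 toward the parent) and run the full grid:

```python
import screenval as sv
from screenval.pipeline import RunConfig, run_validation, render_report

cfg = RunConfig(
    sim=sv.default_sim_config(n_participants=6000, seed=3),
    n_boot=1000,
    seed=3,
)
print(render_report(run_validation(cfg).report))
```

```
contrast,reporter,scale,sex,n_pos,n_neg,threshold,auc,ci_low,ci_high,p_one_sided,p_two_sided,ratio_met,note
sensitivity,parent,dsm_affective_13,pooled,303,2727,0.800,0.991,0.988,0.993,0.999,<0.002,True,
sensitivity,child,dsm_affective_13,pooled,285,2565,0.800,0.666,0.633,0.695,<0.001,<0.002,True,
sensitivity,clinician,dsm_affective_13,pooled,187,1683,0.800,0.957,0.946,0.968,0.999,<0.002,True,
specificity,parent,dsm_affective_13,pooled,303,920,0.800,0.983,0.977,0.988,0.999,<0.002,False,ratio not met: all controls used
specificity,child,dsm_affective_13,pooled,285,1003,0.800,0.616,0.581,0.653,<0.001,<0.002,False,ratio not met: all controls used
specificity,clinician,dsm_affective_13,pooled,187,742,0.800,0.927,0.908,0.944,0.999,<0.002,False,ratio not met: all controls used
strict_specificity,parent,dsm_affective_13,pooled,159,920,0.800,0.982,0.975,0.988,0.999,<0.002,False,ratio not met: all controls used
strict_specificity,child,dsm_affective_13,pooled,228,1003,0.800,0.616,0.576,0.658,<0.001,<0.002,False,ratio not met: all controls used
strict_specificity,clinician,dsm_affective_13,pooled,138,742,0.800,0.917,0.895,0.937,0.999,<0.002,False,ratio not met: all controls used
```

Read each row like a validation-table row: the parent-report scale is an
excellent predictor of the parent's own diagnoses (sensitivity AUCROC
0.991; the one-sided p of 0.999 says virtually every bootstrap AUCROC
crossed 0.8, so there is no evidence of sub-threshold performance) and of
the clinician consensus (0.957), but only a weak predictor of the child's
self-reported diagnoses (0.666, with `<0.001` meaning *no* bootstrap
value reached 0.8 — performance is significantly below threshold). That
is the informant-discrepancy signature the generator is built to emulate;
the same cohort's parent × child depression agreement table makes it
explicit (κ = 0.099):

```
          child +  child -
parent +       42      261
parent -      243     5454
```

The same steps are available from the shell:

```sh
screenval simulate --n 6000 --seed 3 --out cohort.csv
screenval build-contrast --cohort cohort.csv --kind sensitivity --reporter parent --ratio 0.10 --seed 1 --out contrast.csv
screenval roc-test --scores-file scores.csv --threshold 0.8 --n-boot 1000 --seed 1
screenval run --config run.yaml --out-dir results/
```

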