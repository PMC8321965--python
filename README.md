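# rcads-brief

Derivation, evaluation and scoring of a brief (11-item) anxiety/depression
screen for adolescents, built from the 47-item RCADS item bank.

Anxiety and depressive disorders are the most common mental-health problems
in 11–17-year-olds, and the people best placed to spot them — school and
primary-care staff — need questionnaires that are short, easy to score, and
accurate against a diagnostic-interview criterion. This package is for
researchers and psychometricians who develop or evaluate such short forms
with a two-sample design (a community cohort versus a clinic-referred cohort
with interview-confirmed diagnoses, each adolescent reported on by
themselves and a parent). It implements the complete pipeline as a tested
library:

- **synthetic cohorts** — a seeded graded-response generator (ordinal score
  = number of thresholds below loading × trait + noise, with correlated
  anxiety/depression traits, diagnosis shifts, two correlated informants,
  and MCAR missingness) so every stage is testable without clinical data;
- **item reduction** — item-total correlations r(xᵢ, Σx), point-biserial
  discrimination r(xᵢ, D) against the diagnosis indicator D, partials
  r(xᵢ,D·z) for gender/age, and the retention rule
  (r_it > 0.70 ∨ r_pb > 0.30) ∧ missing < 10%;
- **ROC machinery** — empirical Mann–Whitney AUC, midpoint thresholds,
  sensitivity-prioritised tiered cut-offs (sens/spec > 0.8/0.7, else
  > 0.7/0.7, else > 0.7/0.6), subgroup repeats, and the a-priori sample
  size n = (z₁₋α/₂√V₀ + z₁₋β√V₁)²/(AUC₁ − ½)² with Obuchowski's binormal
  variance;
- **subset search** — nested candidates by greedy removal of the weakest
  item, with content-overlap exclusions and selection over (tier, AUC,
  brevity);
- **augmentation** — likelihood-ratio tests between nested logistic
  regressions (χ² = deviance difference) for suicidal-ideation, impact and
  duration add-ons and for adolescent+parent informant combination;
- **psychometrics** — McDonald's ω = (Σλ)²/((Σλ)² + Σθ) from a one-factor
  minres fit with bootstrap CIs, convergent/divergent validity against the
  MFQ, criterion-validity ROC grids, and MCAR comparability checks;
- **scoring** — the final 11-item screen (anxiety: RCADS 18, 45, 35, 34,
  24, 20; depression: RCADS 19, 6, 29, 2, 21; optional distress and school
  impact items) with the published informant- and gender-specific integer
  cut-offs.

## Worked example

Score one adolescent girl on the built-in screen:

```python
from rcads_brief import default_screen, score_screen

responses = {"RCADS18": 2, "RCADS45": 1, "RCADS35": 2, "RCADS34": 0,
             "RCADS24": 1, "RCADS20": 2,                      # anxiety items
             "RCADS19": 3, "RCADS6": 2, "RCADS29": 1, "RCADS2": 2,
             "RCADS21": 3,                                    # depression items
             "IMP_DISTRESS": 2, "IMP_SCHOOL": 1}              # impact items

result = score_screen(responses, default_screen(),
                      gender="female", informant="adolescent")
print(result.anxiety_score, result.anxiety_positive)
print(result.depression_score, result.depression_positive)
print(result.total_score, result.total_positive)
print(result.total_plus_impact_score, result.total_plus_impact_positive)
```

prints

```
8 False
11 True
19 True
22 True
```

Her anxiety score of 8 sits below the girls' anxiety cut-off (≥ 9), but the
depression score 11 (cut-off ≥ 9), total 19 (≥ 14) and total-plus-impact 22
(≥ 18) all screen positive — and because the depression scale is positive,
`result.risk_advisory` carries a reminder that a proper risk assessment is
needed (the screen itself contains no suicidal-ideation items). The a-priori
ROC power calculation behind the design,
`required_n_per_group(0.70, 0.80, 0.05, two_sided=True)`, prints `30`
participants per group.

## The analysis pipeline

Numbered drivers under `analysis/` run the whole derivation on a synthetic
cohort and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1   # cohort.csv + summary
python analysis/02_item_reduction.py  --seed 1   # item_stats.csv, eligible pools
python analysis/03_subset_selection.py --seed 1  # subset_evaluations.csv, selection
python analysis/04_augmentation.py    --seed 1   # nested logistic reports
python analysis/05_psychometrics.py   --seed 1   # omega, validity, criterion grid
python analysis/06_score_screen.py    --seed 1   # derived cut-offs, screen results
```

On seed 1 the pipeline retains 13/31 anxiety and 10/10 depression candidates
(strongest anxiety item RCADS18, discrimination 0.47), selects subsets
containing all planted screen items (anxiety AUC 0.84, tier T1; depression
AUC 0.90, tier T1, both verified on parent-report), finds that the two
impact items improve the 11-item total (χ²(2) = 28.9, p < 0.01) and that
parent-report adds to adolescent-report (χ²(1) = 29.9, p < 0.01), and
reports ω between 0.81 (clinic depression subsample) and 0.89 (community)
for the 11-item total.

The same stages are exposed as a CLI: `rcads-brief simulate|derive|score`
(see `rcads-brief --help`).

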