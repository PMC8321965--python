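# Methods

## The problem

Anxiety and depressive disorders are the most common mental-health problems
in adolescence, and school or primary-care screening needs instruments that
are short (well under 15 items), easy to score, and accurate against a
diagnostic-interview criterion. This package implements the full derivation
pipeline for such a brief screen from a longer item bank — the 47-item
RCADS (Revised Children's Anxiety and Depression Scale, 0–3 ordinal items in
six disorder subscales), with MFQ suicidal-ideation items (0–2) and symptom
impact/duration questions (0–3) as candidate add-ons — using the two-sample
design of a community cohort (no diagnostic flags) versus a clinic-referred
cohort in which every adolescent carries a current anxiety and/or depressive
diagnosis, each reported on by the adolescent and a parent.

The final instrument scored by `rcads_brief.scoring` is the published
11-item screen: six anxiety items (RCADS 18, 45, 35, 34, 24, 20; range
0–18), five depression items (RCADS 19, 6, 29, 2, 21; range 0–15), total
0–33, optionally extended by two impact items (distress and school
interference; 0–39), with informant- and gender-specific integer cut-offs
(score ≥ threshold screens positive).

## Pipeline

1. **Item reduction** (`reduction`). On the pooled frame — community plus
   the clinic subsample carrying the relevant diagnosis, one informant at a
   time — each candidate item gets: the Pearson correlation with its scale
   total (uncorrected, i.e. the item stays in the total; a corrected variant
   is available behind a flag), the point-biserial discrimination index
   (Pearson correlation with the 0/1 diagnosis indicator), first-order
   partials of that index controlling gender and age group (one covariate at
   a time), and the missing fraction. Items are retained when
   (item-total > 0.70 OR discrimination > 0.30) AND missing < 10%;
   thresholds are strict and configurable. All statistics use pairwise
   deletion: exactly the persons complete on the variables involved.

2. **Subset search** (`subsets`). User-supplied content-overlap exclusion
   pairs are resolved first (the lower-discrimination member is dropped;
   ties by lower item-total, then item id). Nested candidate subsets then
   shrink from the full eligible pool by removing the weakest remaining item
   one at a time. Each subset's sum score (persons missing a constituent
   item are dropped for that evaluation) is judged by empirical ROC analyses
   overall and within gender and age strata. A subset *meets criteria* when
   its overall AUC ≥ 0.7, its tiered cut-off exists (see below), and every
   non-empty stratum's AUC ≥ 0.7.

3. **Cut-off selection** (`roc`). Thresholds are midpoints between
   consecutive distinct observed scores plus the two extremes; a respondent
   is positive when score > threshold, so on integer sum scores the selected
   cut-offs are half-integers and "> k − 0.5" equals the integer rule
   "≥ k". Selection is sensitivity-prioritised through a tier ladder —
   T1: sensitivity > 0.8 and specificity > 0.7; T2: > 0.7/0.7;
   T3: > 0.7/0.6 (strict inequalities) — taking, within the first non-empty
   tier, the threshold maximising sensitivity + specificity, ties resolved
   toward the lower cut-off; if no tier is attainable, the global Youden
   optimum is reported with tier NONE. AUC is computed in the Mann–Whitney
   form (ties count half), which equals the trapezoidal area under the
   empirical curve.

4. **Final selection**. Among candidate subsets that meet criteria the
   default rule picks the best tier, then the highest overall AUC, then the
   fewest items. Rationale: subsets are compared by their discriminative
   ability (the AUC ≥ 0.7 gate is the stated subset criterion; the tier
   ladder expresses the screening priority on sensitivity), and brevity only
   breaks ties — a pure "smallest subset passing minimal criteria" rule
   (available as `rule="smallest"`) collapses onto 1–3 items whenever
   individual items are strong, which no short-form developer would accept.
   The adolescent-report winner is then re-evaluated with the same items on
   parent-report (common items across informants being practically
   valuable), and the parent-optimal subset is reported alongside.

5. **Augmentation** (`augmentation`). Add-on items (suicidal ideation
   against the depression diagnosis; impact/duration against any diagnosis)
   are screened by the same discrimination/missingness rule, 0–2 items being
   linearly rescaled to 0–3 first (0 → 0, 1 → 1.5, 2 → 3). Incremental
   value is tested by likelihood-ratio tests between nested unpenalised
   logistic regressions of case membership: base sum score first, add-ons
   entered as separate predictors (per-unit odds ratios are reported; the
   complete-case set is fixed across both fits so the test is valid).
   Informant combination uses the same machinery at the dyad level:
   adolescent sum score, then + parent sum score. A conservative α = 0.01
   is used throughout, matching the analysis convention for samples of this
   size.

6. **Psychometrics** (`psychometrics`). McDonald's ω from a one-factor
   minimum-residual (minres) fit to the item covariance matrix,
   ω = (Σλ)² / ((Σλ)² + Σθ), with a seeded nonparametric person-bootstrap
   percentile 95% CI (default 1000 resamples). Convergent/divergent validity
   is the Pearson correlation of each scale score with the MFQ total
   (computed from raw 0–2 responses before any rescaling), per sample
   stratum. Criterion validity re-uses the subgroup ROC grid across scale
   definitions. The missing-data check compares full completers with
   partial completers by pooled-variance t-tests on scale means and by a
   Fisher-z comparison of the anxiety–depression correlation between the
   completion groups; data are flagged MCAR-consistent when nothing is
   significant at 0.01.

7. **Scoring** (`scoring`). Sum scores with no proration: a missing
   constituent item leaves that scale (and any total containing it)
   undefined rather than imputed. Classification is monotone in the score.
   Respondents whose gender is outside the published threshold table are
   refused unless the caller explicitly selects a threshold row
   (`threshold_gender`), and a positive depression score always carries a
   risk-assessment advisory — suicidal-ideation items are not part of the
   screen, so a negative screen says nothing about self-harm risk.

## A-priori sample size for a ROC analysis

`required_n_per_group` solves the binormal power equation for testing
H0: AUC = 0.5 with Obuchowski's variance approximation,
V(A) = 0.0099·e^(−a²/2)·[(5a² + 8) + (a² + 8)/κ] per case, a = √2·Φ⁻¹(A),
equal group sizes (κ = 1):

    n = (z₁₋α/₂ √V(0.5) + z₁₋β √V(A₁))² / (A₁ − 0.5)².

At A₁ = 0.70, power 0.80, two-sided α = 0.05 the continuous solution is
30.29, reported to the nearest whole participant as 30 per group — the
convention used when this calculation is reported in study protocols
(`rounding="ceil"` gives the strict smallest integer whose power reaches the
target). The same design point is checked against the pROC implementation
of this calculation in development.

## The synthetic cohort generator

No response-level data are distributed with the study design this package
implements, so `synthetic cohorts` are first-class: every pipeline stage is
exercised end-to-end on generated data with known structure.

Mechanism (graded-response style): each adolescent has latent anxiety and
depression traits, bivariate normal with correlation ρ (default 0.65,
reflecting the strong anxiety–depression comorbidity in adolescents). A
diagnosis shifts the corresponding trait by a standardized effect (defaults:
anxiety 1.4 SD, depression 1.8 SD — chosen so the 6-item anxiety and 5-item
depression sum scores land at AUC ≈ 0.81 and ≈ 0.88 against their
diagnoses, the accuracy range reported for brief internalizing screens in
this design). Females and older adolescents shift both traits (+0.35 and
+0.25 SD). An item's latent response is loading × trait + N(0, 1) and the
ordinal score counts the thresholds below it, giving closed-form category
probabilities for test oracles. Default thresholds place realistic
community endorsement rates (e.g. anxiety items ≈ 45/30/15/10% across
categories 0–3). Impact and duration items load on a general severity
composite of the two traits plus an extra +0.7 SD shift for clinic members:
referral requires impairment, so impact items carry signal beyond the
symptom traits — the mechanism behind their incremental contribution in the
nested logistic tests. Parent reports keep the diagnosis and demographic
shifts and attenuate only the person-specific trait deviation (informant
correlation 0.6 given group), so informants disagree about the child, not
about the design; this is what lets parent-report discriminate as well as
adolescent-report rather than being a strictly noisier copy. Missingness is
MCAR (default 2% of cells). Diagnosis flags in the clinic sample follow the
exact joint distribution matching the marginal rates (93.5% anxiety, 32.9%
depression) with at least one flag per member.

Default sample shape: 214 community and 246 clinic dyads; 57.4%/76.8%
female and 30.8%/52% older in community/clinic respectively.

Eleven items are *planted* with high loadings (anxiety 0.95–1.30, depression
0.95–1.05); the remaining candidates fall in weaker tiers (0.20–0.55) so
per-item discrimination spans the range a full-length item pool shows in
this design (planted ≈ 0.35–0.47 point-biserial, distractors straddling the
0.30 eligibility threshold). Loadings were calibrated once against those
printed ranges and then frozen.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: recruitment and opt-out consent bias, school
clustering, MNAR missingness (e.g. instruments introduced mid-study),
multidimensional anxiety (one anxiety trait stands in for the
SEP/GAD/PD/SOC facet structure, so subgroup heterogeneity between anxiety
disorders is absent), informant-specific item biases, and the pattern of
high item-total with low discrimination for the same item (both statistics
track the single loading here, so they cannot be decoupled as they are in
real item pools). Because the synthetic distractor items carry genuine
(weak) signal and no human content-overlap judgment prunes them, the
selected synthetic subsets are typically somewhat longer than 6 + 5 items;
the planted items rank at the top and are contained in the selection.

## Numerical choices

- **minres omega.** The covariance matrix is normalised to unit average
  variance before optimisation (scale-free tolerances; exact scale
  invariance of ω). Loadings are bounded by the communality constraint
  |λᵢ| ≤ √(0.999·Sᵢᵢ) — without the bound the off-diagonal-only objective
  is unidentified for near-diagonal matrices. A Heywood case is raised as an
  error when a loading pins at its bound *and* the off-diagonal residuals
  show gross misfit (> 0.1 of the largest variance); a pinned loading with
  negligible residuals is noise-fitting on an essentially unifactorial or
  uncorrelated matrix and passes through. Omega is computed on complete
  cases for the scale (pairwise covariance matrices need not be positive
  definite); the per-item complete-case floor can be relaxed for long
  scales in small subsamples (`min_persons`).
- **Logistic fits.** statsmodels Newton MLE (tolerance 1e-10); on singular
  designs (constant or duplicated predictors) the fit falls back to BFGS,
  where the deviance remains well defined along the flat direction.
  Complete separation raises an error rather than returning a silently
  divergent fit.
- **Tie-breaks.** Greedy removal order: lowest discrimination, then lowest
  item-total, then lexicographic item id. Cut-off ties within a tier:
  lower cut-off. Subset-selection ties: fewer items.
- **Degenerate inputs.** Zero-variance items raise undefined-correlation
  errors naming the item; empty case or control groups raise grouping
  errors; a covariate perfectly correlated with item or outcome raises a
  degenerate-covariate error; strata with no cases or no controls are
  skipped with a warning, and strata under 30 per group carry an
  `underpowered` flag (the a-priori minimum above).

## Problem sizes

The test suite and analysis drivers run at the design's native scale (214 +
246 dyads, two informants). Monte-Carlo properties use 20 seeded cohorts
(planted-item recovery, augmentation direction, MCAR consistency) and 100
seeded cohorts for the false-positive rate of the 0.01-level nested test;
oracle-equivalence checks use 1,000 random ROC instances of ≤ 50 scores and
100 random small logistic problems. Bootstrap CIs default to 1,000
resamples (400 in the psychometrics driver; 50–200 in fast tests).

## Known limitations

- The greedy search is one-pass by discrimination rank; it does not revisit
  removals or search combinatorially (by design — the derivation procedure
  it implements is greedy).
- Empirical midpoint ROC only: no smoothed/binormal curves, partial AUC, or
  cross-validated AUC, so long scales in small strata can print coarser
  cut-offs than a smoothed analysis would.
- Suicidal-ideation add-ons: in the synthetic world any item sharing the
  depression trait adds detectable conditional information at these sample
  sizes, so the nested test on the best ideation item is usually
  significant — unlike the borderline null this design reported on real
  data. The generator has no mechanism for "discriminates marginally but
  adds nothing beyond the symptom items" short of hand-tuning that item's
  loading down, which was not done.
- The RCADS-25 composition is not bundled (it is not part of this item
  bank's sources); `ScaleDefinition` accepts any user-supplied item list
  for the criterion-validity comparison.
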