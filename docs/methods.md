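# Methods

## The screening problem

Impaired iron transport (IIT) is defined as transferrin saturation (TSAT)
below 20%, irrespective of ferritin. The package evaluates how well routine
red-cell indices — primarily the red cell distribution width (RDW, the
coefficient of variation of red-cell volume: 100 · SD(MCV)/MCV) — identify
IIT in adult heart-failure patients who are *not* anaemic by the WHO
definition (Hb < 13 g/dl in men, < 12 g/dl in women, strict inequalities).
The clinical question is asymmetric: a surrogate is most useful if a *normal*
RDW can safely exclude IIT, so the negative predictive value (NPV) and its
dependence on renal function carry most of the weight.

## Cohort model and derived quantities

A cohort is a per-patient table with demographics, haematology (Hb, Hct,
RDW, MCV, MCHC), iron panel (serum iron, ferritin, transferrin, TSAT, TIBC),
renal values and LVEF. Derived quantities:

* **TSAT** = 100 · serum iron / TIBC (%), used only when a measured TSAT is
  absent; ratios above 1 are clipped to 100% (laboratory rounding).
* **eGFR** by the 4-variable IDMS-traceable MDRD equation,
  175 · Cr^−1.154 · age^−0.203 · 0.742 (female) · 1.212 (black), in
  ml/min/1.73 m². The race multiplier defaults to off. MDRD rather than
  CKD-EPI because it remains the convention in heart-failure laboratories;
  no alternative formula is implemented.
* **eGFR strata**: half-open bins [0,30), [30,60), [60,90), [90,∞) so every
  value maps to exactly one stratum (clinical shorthand like "30–59" vs
  "30–60" is ambiguous at the boundary; half-open intervals resolve it).
* **Labels**: IIT ⇔ TSAT < 20 (strict); guideline iron deficiency ⇔
  ferritin < 100 µg/L, or ferritin in the inclusive band [100, 299] µg/L
  with TSAT < 20.

Eligibility keeps adults (age ≥ 18) who are non-anaemic and have a
resolvable TSAT; records flagged with a non-laboratory exclusion reason
(pregnancy, transfusion, inflammation, cardiogenic shock…) are removed
first. Every removal is logged with its reason and the filter is idempotent.
Missing RDW/eGFR records are dropped (and logged) before ROC analysis; no
imputation anywhere.

## ROC and AUC

Candidate thresholds are midpoints between adjacent distinct score values
plus sentinels outside the observed range, so tied scores share a threshold
and the curve always contains the (sens 1, spec 0) and (sens 0, spec 1)
corners. AUC is computed two independent ways — trapezoidal integration of
the curve, and pairwise concordance (ties count ½, via the rank-sum
identity) — which agree exactly, ties included; the test suite asserts this
equivalence to 1e−12 on randomized instances and cross-checks against
scikit-learn. Directions: RDW is higher-is-positive; MCV and MCHC
lower-is-positive (both fall with iron-deficient erythropoiesis).

Marker combinations use an additive logistic score fitted by maximum
likelihood; the linear predictor is scored as higher-is-positive. Perfect
separation is flagged in the metadata and the score is still returned (via a
weakly ridge-penalized refit when the unpenalized fit fails outright).
Combination is deliberately simple — the question is only whether MCV/MCHC
add discrimination beyond RDW, not to build a tuned classifier.

## Cutoff selection

The optimal cutoff minimizes the Euclidean distance
√[(1−sens)² + (1−spec)²] from the operating point to the ideal ROC corner,
scanned over all candidate thresholds. Ties are broken toward the larger
threshold, i.e. the more specific rule (so an uninformative marker yields
the all-negative rule, never the all-positive one). The fitted cutoff is
applied *inclusively*: predicted positive ⇔ score ≥ cutoff.

Cross-validation repeats a simple unstratified random split 200 times:
training half = first ⌈n/2⌉ of a permutation, cutoff fitted there,
sensitivity/specificity measured on the held-out half; replicates with a
single-class half are skipped and logged, and fewer than 10 completed
replicates is an error. The reported cutoff is the arithmetic mean of the
training cutoffs (rounded to one decimal in reports); mean held-out
sensitivity/specificity are reported alongside as the honest estimate of
out-of-sample performance, and the full-data optimum is serialized next to
the mean for comparison — with ~800 records the two typically differ by
less than 0.2%.

## Diagnostic performance

Standard 2×2 derivations: sens = TP/(TP+FN), spec = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), prevalence = (TP+FN)/n. Ratios with a
zero denominator are reported as missing with a warning rather than as 0 or
1. Report percentages round half-away-from-zero to integers (the convention
of clinical tables; 64.49 → 64, 67.56 → 68); unrounded fractions are always
serialized alongside. Exact binomial Clopper–Pearson 95% intervals accompany
each proportion — an extension beyond the usual bare percentages, included
because stratified NPVs at n ≈ 60 are otherwise easy to over-read.

The stratified report computes the same metrics per eGFR stratum plus the
marker's mean ± SD per stratum; the quadrant table cross-tabulates
marker </≥ cutoff against configurable eGFR groups (default split at 60),
reporting each cell's share of the cohort and its IIT prevalence.

## Synthetic cohort generator

The generator emulates the *structure* of a hospitalized non-anaemic HF
cohort, not record-level realism. One seeded stream, fixed draw order,
bit-identical cohorts per seed.

* **TSAT** (the primitive iron variable) is log-normal, location 3.178 and
  scale 0.49 on the log scale → median ≈ 24%, P(TSAT < 20) ≈ 0.355. Its
  location drifts down by 0.05 per 10 ml/min of eGFR below 90 (centred so
  the marginal prevalence is unchanged): IIT prevalence rises from ≈ 0.25
  in the ≥90 stratum to ≈ 0.51 below 30, reproducing the observed ~7
  ml/min eGFR gap between IIT and non-IIT patients. Without this coupling a
  fixed cutoff's NPV would *rise* as eGFR falls (an equal upward shift of
  both class distributions thins the positive tail below the cutoff faster
  than the negative one), contradicting the clinical picture.
* **eGFR** is drawn by stratum (probabilities 0.137/0.399/0.386/0.078 from
  best to worst) then uniformly within [90,120], [60,90), [30,60), [15,30);
  creatinine is back-solved through MDRD.
* **RDW** = 13.7 + 1.1·1[IIT] + 0.18·(renal deficit) + noise, floored at a
  physiologic 11.0%, where renal deficit = max(0, (90−eGFR)/10). The noise
  is a mean-centred gamma (shape 4, right-skewed, matching RDW's long right
  tail) whose SD grows from 1.1% at preserved eGFR by 0.35% per deficit
  unit — RDW spread is markedly larger in renal dysfunction. The 13.7
  baseline places the overall median at ≈ 14.2 (observed ≈ 14.0) and the
  population-optimal Euclidean cutoff at ≈ 14.2%; the resulting RDW AUC for
  IIT is ≈ 0.67 at the study size.
* **Hb** is normal per sex (14.3/13.4 ± 1.1 g/dl, slightly lower in IIT)
  truncated above the WHO threshold by inverse-CDF sampling, so generated
  cohorts pass the eligibility filter unchanged.
* **Couplings**: serum iron = TSAT · TIBC/100 exactly; TIBC log-normal,
  higher when TSAT is low; ferritin log-normal, lower when TSAT is low;
  MCV and MCHC mildly lower in IIT (−1.6 fl, −0.5 g/dl) — directions as
  observed, magnitudes set so RDW remains the most discriminative of the
  three indices, matching the reported ROC ordering.

What the generator does **not** model: comorbidity and medication,
longitudinal structure, measurement error correlated across analytes, the
ferritin–inflammation axis, anaemic patients. Tests passing on synthetic
cohorts therefore validate the *machinery* (filters, ROC, cutoff CV,
stratified metrics) and the qualitative renal gradient, not real-data
performance; the printed-count worked examples are the only contact with
the real cohort's numbers.

## Problem sizes and numerical choices

Default analyses use the study-sized cohort n = 797 with 200 CV replicates;
distributional checks in the tests use n = 10,000 and 10–20 seeds, which
keeps the whole suite under ~10 s while making the stochastic bands
(prevalence 0.31–0.39, AUC 0.62–0.76, mean cutoff 13.6–15.0, monotone NPV
gradient) comfortably stable. Exact-equivalence assertions use 1e−12;
tie detection in the cutoff scan uses the same tolerance. Degenerate inputs
fail loudly: single-class labels, empty cohorts, zero-margin tables,
non-positive creatinine. Two-group tests default to the uncorrected Pearson
chi-square (the classic large-sample form; Yates correction available as a
flag) and the pooled-variance t-test (Welch as a flag); the "auto" method
picks Fisher's exact test when any expected cell is < 5 and the
Mann-Whitney U when either group's |skewness| ≥ 1.

## Known limitations

* The generator's marginals are fitted to printed summary statistics, not to
  raw data; joint behaviour beyond the modelled couplings is a choice.
* The logistic combination reports in-sample AUC; with two predictors and
  n ≈ 800 the optimism is small but nonzero.
* The Euclidean criterion weights sensitivity and specificity equally; no
  cost-weighted or Youden alternative is implemented.
* Split-half CV estimates cutoff variability but, by averaging training
  cutoffs, still reports a single operating point; the held-out
  sensitivity/specificity means are the less optimistic companion numbers.
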