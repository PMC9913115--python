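# romma

Risk stratification and Oncotype DX triage for ER-positive, HER2-negative
breast cancer from routine histopathology.

The Oncotype DX (ODX) 21-gene recurrence score guides adjuvant chemotherapy
decisions in ER+/HER2− breast cancer, but the assay costs thousands of
dollars and is unavailable in much of the world. The Magee equations are
published multivariable linear models that estimate the ODX recurrence
score from variables every pathology report already contains — Nottingham
score, tumor size, semi-quantitative ER/PR immunohistochemistry, HER2
status and Ki-67. This package implements the Rochester Modified Magee
algorithm (RoMMa) built on them:

1. **Score**: evaluate each modified Magee equation whose inputs are
   present,

   `score_k = β₀ᵏ + β₁ᵏ·NS + β₂ᵏ·ER_H + β₃ᵏ·PR_H + β₄ᵏ·size + β₅ᵏ·Ki67 + γᵏ(HER2)`,

   where ER_H and PR_H are *modified* H-scores (dominant stain intensity
   0–3 × percent positive cells, range 0–300), and average the computable
   equations into the **average Modified Magee score (aMMs)**.
2. **Stratify**: aMMs ≤ 12 → very low risk, 12 < aMMs ≤ 18 → low risk,
   aMMs > 18 → high risk; in parallel, TAILORx-informed ODX categories
   (ODX < 11 very low; 11 ≤ ODX < 16 low; 16–25 low if age > 50 and high
   if age ≤ 50; ODX > 25 high).
3. **Triage**: very-low aMMs → ODX testing not indicated; low → testing
   conditional on clinical/pathologic context; high → testing indicated.
4. **Evaluate**: on cohorts with both scores, the full concordance
   calculus — 3×3 contingency and recurrence tables, per-category and
   pooled recurrence rates, uncorrected Pearson chi-square comparisons,
   Kaplan–Meier / log-rank disease-free-survival comparisons, and
   forego-testing strategy metrics (sensitivity, specificity, PPV, NPV,
   two-point AUC = (sensitivity + specificity)/2, fraction of patients
   spared testing) under the assume-correct-above-cutoff rule.

It is aimed at pathologists and biostatisticians studying testing-triage
strategies, and usable as a plain calculator for individual patients.

## Worked example

```python
from romma import TumorProfile, compute_amms, modified_hscore

profile = TumorProfile(
    nottingham_score=4,
    tumor_size_cm=1.4,
    er_hscore=modified_hscore(3, 95),   # 285
    pr_hscore=modified_hscore(2, 70),   # 140
    ki67_percent=8.0,
)
result = compute_amms(profile)
print(round(result.amms, 1))
```

Running `python examples/01_score_a_patient.py` prints:

```
per-equation scores:
  new_magee_1: 13.5
  new_magee_2: 16.3
  new_magee_3: 19.4
aMMs (average Modified Magee score): 16.4
aMMs risk category: low
triage decision:    odx_conditional
```

All three equations were computable (Ki-67 was available); their average,
16.4, falls in the 12–18 low-risk band, so ODX testing *may* add utility
for this patient and should be weighed against the clinical picture. The
other scripts in `examples/` walk through cohort-level evaluation,
stochastic cohort simulation, and survival comparison; for instance
`examples/02_cohort_evaluation.py` prints, on the bundled synthetic
study-structured cohort:

```
forego testing at aMMs <= 12: sensitivity 89%, NPV 98%, AUC 0.94, 17% of patients avoid testing
forego testing at aMMs <= 18: sensitivity 53%, NPV 92%, AUC 0.76, 66% of patients avoid testing
```

i.e. skipping the assay in very-low-risk patients would spare 17% of the
cohort the test while missing 11% of truly high-ODX patients, all of whom
would still be flagged non-high with 98% negative predictive value.

## Command line

A thin CLI wraps the library:

```bash
romma fixture cohort.csv                 # deterministic study-structured cohort
romma score cohort.csv scored.csv        # adds amms, categories, triage columns
romma triage cohort.csv                  # per-patient decisions to stdout
romma evaluate cohort.csv --out-json report.json
romma simulate sim.csv --n 1000 --seed 7 --mode feature_level
```

Cohort files are plain CSV/TSV with canonical lower-snake headers (see
`romma.cohort.COLUMNS`); empty fields mean *not recorded*, never zero.

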