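# Methods

## The model

The package evaluates the modified Magee equations: published linear
regressions that estimate the Oncotype DX (ODX) recurrence score from
routine histopathology. Each equation has the form

    score = intercept + Σ weight_v · value_v + her2_offset(status)

over a subset of {Nottingham score, tumor size (cm), modified ER H-score,
modified PR H-score, Ki-67 (%)}. The *modified* H-score is the dominant
stain intensity grade (0–3) multiplied by the percent of positive tumor
cells, range 0–300 — a single-term simplification of the classical
three-term H-score (which is also provided, for comparison, as
`classical_hscore`). No clamping is applied to equation outputs.

The **average Modified Magee score (aMMs)** is the arithmetic mean of every
equation whose required variables are present. The missing-data rule is
deliberate: Ki-67 absent (as opposed to measured zero) drops the
Ki-67-bearing equations rather than evaluating them at 0, and the
contributing equation set is always reported (`MageeResult.equations_used`)
so reduced-input scores are auditable.

Coefficients are configuration, not code. The shipped JSON transcribes the
three "new Magee" equations (intercepts 15.31385 / 18.8042 / 15.2999 with
their published weights and HER2 offsets), used here with modified-H-score
inputs. Users can load alternative sets with `CoefficientSet.from_json`;
nothing in the package refits coefficients. Mitotic count is carried in the
data model (it is part of the eligibility-relevant pathology record) but no
shipped equation weights it directly — it enters through the Nottingham
score, of which it is a component.

## Risk categories and triage

aMMs bands: very low ≤ 12 < low ≤ 18 < high, boundaries inclusive as
written, compared against the *unrounded* score (rounding to one decimal is
display-only, avoiding boundary artifacts at e.g. 12.04). ODX bands follow
the TAILORx age-dependent scheme; age exactly 50 takes the ≤ 50 (high-risk
16–25) branch. The triage decision is a pure function of the aMMs category
— the ODX score, even when present, never feeds back into the decision,
which a property test enforces (no information leakage from the assay the
strategy is meant to avoid).

## Evaluation calculus

Cohorts with both scores are cross-classified into a 3×3 contingency table
with a parallel recurrence-count table. From counts alone the package
derives per-category and pooled lower-risk recurrence rates, discordance
rates, and forego-testing strategy metrics under the
assume-correct-above-cutoff rule: patients at or below the aMMs cutoff are
predicted non-high without testing; everyone above is tested and receives
their actual ODX label. False positives are therefore impossible, so
specificity ≡ 1 and PPV ≡ 1 whenever any patient is predicted positive
(PPV is flagged undefined, not fabricated, when no one is); the AUC is the
two-point trapezoid (sensitivity + specificity)/2. Zero denominators
always surface as flagged `nan`, never silently as 0 or 1.

Association between recurrence and risk scale uses the uncorrected Pearson
chi-square (df = 1); the Yates-corrected variant is available behind a
flag but is not the default, since the uncorrected statistic is the one
that reproduces the reference p-values on these marginal tables. The test
suite additionally brackets the asymptotic p-value inside the exact
fixed-margin permutation distribution's discreteness envelope
[P(S > obs), P(S ≥ obs)].

Disease-free survival treats breast-cancer recurrence as the event and
everything else, including death without recurrence, as censoring (the
cohort schema carries no cause-of-death field, so competing risks are out
of scope). Kaplan–Meier estimation and the two-group log-rank test (ties
by the hypergeometric variance) are delegated to lifelines; both are
verified in the test suite against hand product-limit and
observed-minus-expected tallies. Matched-category comparisons (aMMs group
vs ODX group at the same risk level) use overlapping marginal groups, as in
marginal concordance reporting.

## Eligibility filter

`apply_eligibility` retains records with endocrine therapy, no systemic
chemotherapy, HER2-negative status, and either ≥ 60.0 months of
recurrence-free follow-up or a recurrence at any time. It only filters —
never mutates — and is idempotent. ER positivity is normally asserted
upstream (the package targets ER+ cohorts); an optional check
(`require_er_positive`) treats er_hscore > 0 as positive, since no
universally agreed H-score threshold exists; it defaults off.

## Synthetic cohorts

No patient-level data ship with the package; all cohorts are synthetic and
labelled as such (`SYN…`/`SIM…` ids).

**Exact fixture** (`generate_exact_fixture`): a deterministic 355-patient
cohort whose pipeline-computed 3×3 cell counts are
[[26, 30, 6], [53, 101, 19], [15, 77, 28]] with per-cell recurrences
[[0, 2, 0], [5, 7, 2], [2, 9, 4]] — the category structure of the
reference study population — including the age structure of the high-ODX
column (32 patients ≤ 50 years with ODX 16–25, of whom the 19 in the
low-aMMs row include both of that cell's recurrences; 21 patients with
ODX > 25). Within-cell choices the tables do not pin down (which of the
very-low-row high-ODX patients are young, exact ages, score placement) are
made once, deterministically: all six very-low/high-ODX patients have
ODX > 25 and age > 50, and the 13 remaining young patients sit
non-recurrent in the high/high cell. aMMs targets are evenly spaced
strictly inside each category band and realised as tumor profiles by exact
inversion (below); ODX integers cycle strictly inside each column's band;
recurrence months span (3, 144) and censoring times (60, 160), so every
record passes the eligibility filter.

**Profile inversion** (`profile_for_amms`): between a maximally favourable
anchor (ER-H 300, PR-H 300, Ki-67 0, size 0.5 cm) and a maximally adverse
one (40, 0, 70, 10 cm) every equation is linear at fixed Nottingham score,
so the aMMs along the segment is linear in the interpolation parameter and
any attainable target can be hit exactly by a one-dimensional solve; the
Nottingham score is chosen to leave the parameter closest to mid-range.
With the shipped coefficients the attainable aMMs for a HER2-negative
tumor with in-range pathology is ≈ 9.8–41; reported real-cohort scores
reach a little lower (≈ 6.5), which the transcribed equation set cannot
produce — fixture bands are therefore clipped to the attainable part of
each category band. Category-level statistics are unaffected.

**Stochastic generator** (`generate_cohort`): `category_level` mode draws
the 3×3 cell multinomially (default probabilities = study counts / 355),
places aMMs targets uniformly within clipped bands and ODX uniformly
within column bands (high column split young-16–25 vs > 25 with
probability 32/53), and draws recurrences per cell (default probabilities
= study recurrences / counts); ages are a clipped normal (mean 59, sd 10,
bounds 33–84 — sd chosen freely; only the 50-year threshold matters, and
it is enforced where a cell requires it). `feature_level` mode instead
samples tumor profiles directly: a single left-skewed latent
aggressiveness variable (scaled Beta(1.6, 2.8), reflecting the lower-risk-
dominated case mix of such cohorts) drives grade up, ER/PR down and Ki-67
up with Gaussian jitter, sizes are log-normal (median 1.9 cm), all values
clipped to the observed pathology ranges (ER-H 40–300, Ki-67 0–70, size
0.4–14 cm, NS 3–9); the aMMs is then computed honestly and ODX sampled
conditionally on the resulting category via the row-conditional cell
probabilities. The feature correlations are a modelling assumption — the
reference tables constrain only the category-level joint — so
feature-level mode emulates realistic marginals and a plausible
correlation sign pattern, not the true joint distribution; its aMMs span
is checked only as a soft property (≥ 90% within the observed 6.5–32.3
range). Survival-time generation for Kaplan–Meier property tests
(`synthetic_event_times`) uses exponential times with category-ordered
hazards (0.0003 / 0.00075 / 0.0012 per month) and administrative
censoring; it is purely synthetic.

Consequently, passing tests demonstrate that the algorithms reproduce the
category-level calculus exactly and behave correctly under the stated
models; they say nothing about how well the Magee equations track ODX in
new patients, which only real cohorts can show.

## Numerical and design choices

* All scores at full float precision internally; display rounds (aMMs 1
  d.p., table rates 1 d.p., strategy metrics whole percent, AUC 2 d.p.).
* Strategy forego sets must be downward-closed ({}, {very low},
  {very low, low}) — the strategy is a cutoff, not an arbitrary subset.
* Missing values in cohort files are empty fields; "0" is always a
  measured zero. H-scores may be given directly or as intensity/percent
  pairs; if both, they must agree.
* Chi-square requires both margins positive; log-rank with no events in
  either group returns a flagged-undefined result rather than a number.
* Problem sizes: property tests use 1,000 random tables, the parameter-
  recovery check a single 100,000-patient category-level cohort (3-SE
  multinomial bands), chosen to make sampling-error bounds tight at
  desk-scale runtimes.
* All randomness flows through `numpy.random.default_rng(seed)`;
  identical parameters give bit-identical cohorts.

## Known limitations

* Coefficient transcription is configuration: sites using locally
  re-derived Magee variants must supply their own JSON.
* The evaluation treats the ODX category as ground truth for strategy
  metrics (the assume-correct-above-cutoff rule); it cannot measure ODX's
  own errors.
* Matched-category chi-square/log-rank comparisons use overlapping groups
  and are descriptive, not independent-sample tests.
* No competing-risk or multivariable (Cox) survival modelling; no nodal
  status, LVI or online prognostic calculators in the triage rule —
  discordant clinicopathologic features are a narrative override carried
  as free text, not algorithm input.
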