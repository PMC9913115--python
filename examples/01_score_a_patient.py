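"""Score a single tumor and decide whether Oncotype DX testing is indicated.

Builds a tumor profile from routine pathology, evaluates every modified
Magee equation whose inputs are present, averages them into the aMMs, and
maps the score to a risk category and a triage decision.
"""

from romma import (
    Her2Status,
    PatientRecord,
    TumorProfile,
    compute_amms,
    modified_hscore,
    romma_triage,
)

# A 63-year-old with a 1.4 cm, Nottingham score 4 tumor, strong ER (3+ in
# 95% of cells), moderate PR, Ki-67 of 8%, HER2-negative.
profile = TumorProfile(
    nottingham_score=4,
    tumor_size_cm=1.4,
    er_hscore=modified_hscore(3, 95),   # 285
    pr_hscore=modified_hscore(2, 70),   # 140
    her2=Her2Status.NEGATIVE,
    ki67_percent=8.0,
    mitotic_count=3,
)

result = compute_amms(profile)
print("per-equation scores:")
for eq_id, score in result.per_equation_scores.items():
    print(f"  {eq_id}: {score:.1f}")
print(f"aMMs (average Modified Magee score): {result.amms:.1f}")

patient = PatientRecord(
    patient_id="example-1",
    age_years=63,
    profile=profile,
    followup_months=0.0,   # newly diagnosed; follow-up fields unused here
    recurred=False,
)
assignment = romma_triage(patient)
print(f"aMMs risk category: {assignment.amms_category}")
print(f"triage decision:    {assignment.triage.value}")
# An aMMs <= 12 is very low risk: Oncotype DX testing would likely add no
# clinical utility for this patient; 12-18 would be conditional; > 18 means
# testing is indicated.
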