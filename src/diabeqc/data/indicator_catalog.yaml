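# Candidate quality-of-care indicators for type 2 diabetes in primary care,
# in expert-panel review order, with the panel's mean validity/feasibility
# scores (1-9 scale). An indicator is active iff it was accepted by the panel
# (both means >= 7) AND is programmable from structured EHR fields; the four
# free-text-only indicators and the five discarded candidates are carried as
# inactive catalog entries.
version: 1
candidates:
  - id: p1
    title: At least one measurement of HbA1c in the last year
    family: detection
    validity_mean: 8.7
    feasibility_mean: 7.8
    status: accepted
    programmable: true
  - id: p2
    title: Comprehensive foot evaluation in the last year
    family: detection
    validity_mean: 8.7
    feasibility_mean: 8.2
    status: accepted
    programmable: true
  - id: p3
    title: Referral to the ophthalmologist in the last year
    family: detection
    validity_mean: 8.3
    feasibility_mean: 7.7
    status: accepted
    programmable: true
  - id: disc_microalbuminuria
    title: Screening for microalbuminuria through the albumin/creatinine ratio
    family: detection
    validity_mean: 8.5
    feasibility_mean: 5.7
    status: discarded
    programmable: false
  - id: disc_creatinine_gfr
    title: Measurement of creatinine and glomerular filtration rate
    family: detection
    validity_mean: 8.7
    feasibility_mean: 5.3
    status: discarded
    programmable: false
  - id: p4
    title: Screening for dyslipidemia by measuring total cholesterol in patients
      without previous diagnosis of dyslipidemia
    family: detection
    validity_mean: 8.5
    feasibility_mean: 7.8
    status: accepted
    programmable: true
  - id: np_smoking_counseling
    title: Smoking cessation counseling for current smokers
    family: non_pharmacological
    validity_mean: 8.2
    feasibility_mean: 8.0
    status: accepted
    programmable: false
  - id: disc_alcohol_advice
    title: Advice to moderate alcohol consumption
    family: non_pharmacological
    validity_mean: 6.0
    feasibility_mean: 5.8
    status: discarded
    programmable: false
  - id: p5
    title: Nutritional counseling provided by the nutrition service
    family: non_pharmacological
    validity_mean: 7.8
    feasibility_mean: 7.8
    status: accepted
    programmable: true
  - id: np_exercise_advice
    title: Advice to practice moderate aerobic exercise at least 150 minutes per
      week, unless contraindicated
    family: non_pharmacological
    validity_mean: 8.2
    feasibility_mean: 8.0
    status: accepted
    programmable: false
  - id: np_diet_adherence_registration
    title: Registration of adherence to dietary recommendations
    family: non_pharmacological
    validity_mean: 8.5
    feasibility_mean: 7.0
    status: accepted
    programmable: false
  - id: np_exercise_adherence_registration
    title: Registration of adherence to aerobic physical exercise
    family: non_pharmacological
    validity_mean: 8.5
    feasibility_mean: 7.0
    status: accepted
    programmable: false
  - id: p6
    title: Overweight/obese (BMI >= 25 kg/m2) patients who received metformin,
      unless contraindicated
    family: pharmacological
    validity_mean: 8.7
    feasibility_mean: 8.5
    status: accepted
    programmable: true
  - id: disc_hyperglycemia_management
    title: Patients with HbA1c >= 8 or average fasting glucose >= 140 mg/dl with
      registered diet/exercise recommendations, social-work referral or
      treatment modification
    family: pharmacological
    validity_mean: 8.7
    feasibility_mean: 6.3
    status: discarded
    programmable: false
  - id: disc_hyperglycemia_adherence
    title: Patients with HbA1c >= 8 or average fasting glucose >= 140 mg/dl with
      registered adherence to pharmacological treatment
    family: pharmacological
    validity_mean: 8.5
    feasibility_mean: 6.8
    status: discarded
    programmable: false
  - id: p7
    title: Patients with hypertension receiving an ACE inhibitor or
      angiotensin-receptor blocker, unless contraindicated
    family: pharmacological
    validity_mean: 8.5
    feasibility_mean: 8.5
    status: accepted
    programmable: true
  - id: p8
    title: Patients > 40 years of age with smoking, hypertension or dyslipidemia
      receiving 75-150 mg/day of acetylsalicylic acid, unless contraindicated
    family: pharmacological
    validity_mean: 8.5
    feasibility_mean: 8.2
    status: accepted
    programmable: true
  - id: p9
    title: Patients with total cholesterol > 200 mg/dl prescribed statins,
      unless contraindicated
    family: pharmacological
    validity_mean: 8.2
    feasibility_mean: 8.3
    status: accepted
    programmable: true
  - id: o1
    title: HbA1c < 7% or fasting glucose <= 130 mg/dl in the last 3 measurements
    family: outcome
    validity_mean: 8.7
    feasibility_mean: 8.3
    status: accepted
    programmable: true
  - id: o2
    title: Total cholesterol < 200 mg/dl in the last measurement
    family: outcome
    validity_mean: 8.7
    feasibility_mean: 8.2
    status: accepted
    programmable: true
  - id: o3
    title: Blood pressure < 130/80 mmHg in the last 3 measurements
    family: outcome
    validity_mean: 8.7
    feasibility_mean: 8.5
    status: accepted
    programmable: true
  - id: o4
    title: Overweight/obese (BMI >= 25 kg/m2) patients who lost >= 5% body
      weight in the last year
    family: outcome
    validity_mean: 8.0
    feasibility_mean: 7.7
    status: accepted
    programmable: true
  - id: o5
    title: Composite control - HbA1c < 7% or fasting glucose <= 130 mg/dl, total
      cholesterol < 200 mg/dl and blood pressure < 130/80 mmHg in the last 3
      measurements
    family: outcome
    validity_mean: 8.5
    feasibility_mean: 7.5
    status: accepted
    programmable: true
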