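# RCOG-style comparator (documented approximation).
#
# Every intrapartum/urgent cesarean meets the intermediate-risk criterion and
# is considered for 10 days of LMWH; elective cesareans qualify with any one
# additional risk factor. Mechanical prophylaxis is universal for CS. The
# factor list below uses the RCOG-style cutoffs (age >= 35, BMI >= 30,
# preterm < 37 weeks) rather than the department protocol's; the published
# recoding did not enumerate its exact list, so institutions should edit this
# file to match their own.
name: rcog
mechanical_policy: universal
pharmacologic:
  emergency_triggers_alone: true
  min_minor_alone: 1
  minor_factors:
    - name: age_ge_35
      all: [{field: age, op: ge, value: 35}]
    - name: bmi_ge_30
      all: [{field: bmi, op: ge, value: 30}]
    - name: parity_ge_3
      all: [{field: parity, op: ge, value: 3}]
    - name: pre_eclampsia
      all: [{field: pre_eclampsia, op: is_true}]
    - name: multiple_pregnancy
      all: [{field: multiple_pregnancy, op: is_true}]
    - name: preterm_lt_37wk
      all: [{field: gestational_age_at_delivery, op: lt, value: 37}]
    - name: prolonged_labor_gt24h
      all: [{field: prolonged_labor_gt24h, op: is_true}]
    - name: stillbirth
      all: [{field: stillbirth, op: is_true}]
    - name: medical_comorbidity
      all: [{field: medical_comorbidity, op: is_true}]
    - name: low_risk_thrombophilia
      all: [{field: low_risk_thrombophilia, op: is_true}]
    - name: current_smoker
      all: [{field: current_smoker, op: is_true}]
    - name: gross_varicose_veins
      all: [{field: gross_varicose_veins, op: is_true}]
    - name: current_systemic_infection
      all: [{field: current_systemic_infection, op: is_true}]
    - name: immobility
      all: [{field: immobility, op: is_true}]
    - name: family_history_vte
      all: [{field: family_history_vte, op: is_true}]
    - name: pph_or_transfusion
      any:
        - {field: pph_ml, op: ge, value: 1000}
        - {field: transfusion, op: is_true}
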