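# ACCP-style comparator (documented approximation).
#
# Pharmacologic prophylaxis with 1 major risk factor, 2 or more minor risk
# factors, or 1 minor risk factor at an emergency cesarean. Mechanical
# prophylaxis is rendered universal for the rate comparison. Major/minor
# designations approximate the ACCP postpartum lists; the published recoding
# did not enumerate its exact designations, so edit to match your
# institution.
name: accp
mechanical_policy: universal
pharmacologic:
  min_minor_alone: 2
  min_minor_with_emergency: 1
  major_factors:
    - name: prior_vte_or_high_risk_thrombophilia
      all: [{field: prior_vte_or_high_risk_thrombophilia, op: is_true}]
    - name: immobility
      all: [{field: immobility, op: is_true}]
    - name: medical_comorbidity
      all: [{field: medical_comorbidity, op: is_true}]
    - name: current_systemic_infection
      all: [{field: current_systemic_infection, op: is_true}]
    - name: pph_or_transfusion
      any:
        - {field: pph_ml, op: ge, value: 1000}
        - {field: transfusion, op: is_true}
  minor_factors:
    - name: bmi_ge_30
      all: [{field: bmi, op: ge, value: 30}]
    - name: multiple_pregnancy
      all: [{field: multiple_pregnancy, op: is_true}]
    - name: pre_eclampsia
      all: [{field: pre_eclampsia, op: is_true}]
    - name: current_smoker
      all: [{field: current_smoker, op: is_true}]
    - name: low_risk_thrombophilia
      all: [{field: low_risk_thrombophilia, op: is_true}]
    - name: stillbirth
      all: [{field: stillbirth, op: is_true}]
    - name: prolonged_labor_gt24h
      all: [{field: prolonged_labor_gt24h, op: is_true}]
    - name: gross_varicose_veins
      all: [{field: gross_varicose_veins, op: is_true}]
    - name: family_history_vte
      all: [{field: family_history_vte, op: is_true}]
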