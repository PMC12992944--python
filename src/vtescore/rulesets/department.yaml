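# Department cesarean-section VTE prophylaxis protocol.
#
# Each risk factor scores 1 point unless stated; BMI >= 30 kg/m^2 scores 2
# and is mutually exclusive with the overweight band. The postpartum markup
# (+1 for PPH >= 1000 mL or intraoperative transfusion) is a separate stage:
# it can raise the final score (and so trigger postnatal LMWH) but is not
# known at the time the intraoperative pneumatic cuff is decided.
#
# Tiers: final score < 2 -> early mobilization only; = 2 -> pneumatic cuff;
# >= 3 -> cuff + at least 10 days of prophylactic enoxaparin
# (40 mg daily below 100 kg booking weight, 60 mg at or above).
name: department
version: "1.0"
mechanical_threshold: 2
pharmacologic_threshold: 3
dosing:
  drug: enoxaparin
  duration_days: 10
  weight_cutoff_kg: 100
  dose_below_cutoff_mg: 40
  dose_at_or_above_cutoff_mg: 60
factors:
  - name: age_ge_40
    points: 1
    all: [{field: age, op: ge, value: 40}]
  - name: bmi_25_to_30
    points: 1
    all:
      - {field: bmi, op: ge, value: 25}
      - {field: bmi, op: lt, value: 30}
  - name: bmi_ge_30
    points: 2
    all: [{field: bmi, op: ge, value: 30}]
  - name: parity_ge_3
    points: 1
    all: [{field: parity, op: ge, value: 3}]
  - name: pre_eclampsia
    points: 1
    all: [{field: pre_eclampsia, op: is_true}]
  - name: multiple_pregnancy
    points: 1
    all: [{field: multiple_pregnancy, op: is_true}]
  - name: preterm_lt_34wk
    points: 1
    all: [{field: gestational_age_at_delivery, op: lt, value: 34}]
  - name: prolonged_labor_gt24h
    points: 1
    all: [{field: prolonged_labor_gt24h, op: is_true}]
  - name: stillbirth
    points: 1
    all: [{field: stillbirth, op: is_true}]
  - name: medical_comorbidity
    points: 1
    all: [{field: medical_comorbidity, op: is_true}]
  - name: low_risk_thrombophilia
    points: 1
    all: [{field: low_risk_thrombophilia, op: is_true}]
  - name: current_smoker
    points: 1
    all: [{field: current_smoker, op: is_true}]
  - name: gross_varicose_veins
    points: 1
    all: [{field: gross_varicose_veins, op: is_true}]
  - name: current_systemic_infection
    points: 1
    all: [{field: current_systemic_infection, op: is_true}]
  - name: immobility
    points: 1
    all: [{field: immobility, op: is_true}]
  - name: family_history_vte
    points: 1
    all: [{field: family_history_vte, op: is_true}]
  - name: pph_or_transfusion
    points: 1
    stage: post_operative_markup
    any:
      - {field: pph_ml, op: ge, value: 1000}
      - {field: transfusion, op: is_true}
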