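# Reconstructed risk-factor profiles of the 16 published postpartum VTE cases
# (11 preprotocol, 5 protocol period). Continuous values not stated in the
# case narratives (weight, exact gestational age at term) are plausible
# synthetic fill-ins chosen to leave the factor list unchanged.
# printed_score = score as published; expected_final_score = score implied by
# the tabulated factor list (protocol case 5's published scalar disagrees
# with its own factor annotation; see docs/methods.md).
case_id,period,age,bmi,weight,parity,gestational_age_at_delivery,cs_urgency,pre_eclampsia,multiple_pregnancy,prolonged_labor_gt24h,stillbirth,medical_comorbidity,low_risk_thrombophilia,current_smoker,gross_varicose_veins,current_systemic_infection,immobility,family_history_vte,pph_ml,transfusion,on_antenatal_lmwh,prior_vte_or_high_risk_thrombophilia,vte_event,printed_score,expected_pre_op_score,expected_final_score
1,preprotocol,29,30,77,1,39,elective,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,2,2,2
2,preprotocol,31,27,69,0,29,emergency,0,0,0,0,0,0,0,0,0,0,0,1000,0,0,0,1,3,2,3
3,preprotocol,43,22,56,2,39,elective,0,0,0,0,0,0,0,0,0,0,0,1100,0,0,0,1,2,1,2
4,preprotocol,26,22,56,2,39,elective,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0
5,preprotocol,40,22,56,1,39,elective,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1,2,2,2
6,preprotocol,45,31,79,1,39,elective,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,3,3,3
7,preprotocol,42,30,77,0,39,elective,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,3,3,3
8,preprotocol,46,23,59,0,37,emergency,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1,3,3,3
9,preprotocol,27,22,56,0,39,elective,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1,1,1,1
10,preprotocol,38,28,72,0,39,elective,1,0,0,0,0,0,0,0,0,0,0,1200,0,0,0,1,3,2,3
11,preprotocol,38,27,69,1,39,elective,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,1,1
12,protocol,29,27,69,0,40,emergency,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,2,2,2
13,protocol,39,29,74,0,31,emergency,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,1,4,4,4
14,protocol,39,31,79,1,33,emergency,0,0,0,0,0,0,0,0,0,0,0,3000,0,0,0,1,4,3,4
15,protocol,40,29,74,1,39,elective,0,0,0,0,0,0,0,0,0,0,0,1000,0,0,0,1,3,2,3
16,protocol,40,28,72,1,38,emergency,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,2,2
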