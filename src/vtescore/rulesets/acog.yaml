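# ACOG-style comparator.
#
# Universal pneumatic compression devices for all cesareans; pharmacologic
# prophylaxis only for prior VTE / high-risk thrombophilia. In a cohort where
# those patients are already on antenatal LMWH and excluded before scoring,
# the recoded pharmacologic rate is 0%.
name: acog
mechanical_policy: universal
pharmacologic:
  major_factors:
    - name: prior_vte_or_high_risk_thrombophilia
      all: [{field: prior_vte_or_high_risk_thrombophilia, op: is_true}]
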