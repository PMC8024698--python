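# Default expert weighting scheme for scoring previous studies.
#
# Each category awards `points` when a study fulfils the criterion.
# `applicable_to` restricts a category to a parameter class:
#   T1_T2 — paths from internalizing symptoms at T1 to interaction behavior at T2
#   T2_T3 — paths from interaction behavior at T2 to internalizing symptoms at T3
#     (controlling for earlier symptoms is only meaningful for T2_T3 paths,
#      so that category is removed from the maximum for T1_T2 paths).
# Maximum attainable score: 100 for T2_T3 parameters, 80 for T1_T2 parameters.
categories:
  - name: longitudinal
    points: 10
    details: longitudinal (T1-T2) design rather than cross-sectional
  - name: control_t1
    points: 20
    applicable_to: [T2_T3]
    details: controls for symptoms at T1 (change model); not applicable to T1->T2 paths
  - name: same_time_lag
    points: 5
    details: uses the same 1-year time lag between measurements
  - name: observation
    points: 15
    details: interaction behavior assessed purely by observation (not self-report)
  - name: age_range
    points: 10
    details: early-to-mid adolescent sample (roughly ages 12-16)
  - name: internalizing_scope
    points: 10
    details: internalizing measured as anxiety plus depression, or anxiety only
  - name: covariate_partner_symptoms
    points: 5
    details: controls for the interaction partner's symptoms
  - name: covariate_other_behavior
    points: 5
    details: controls for the other partner's interaction behavior
  - name: community_sample
    points: 10
    details: community (non-clinical) sample
  - name: meta_analysis
    points: 10
    details: evidence comes from a meta-analysis rather than a single study
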