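# Desk-scale analysis conditions: two non-overlapping cohorts of 5,000 with
# 20 child-specific, 20 adult-specific and 8 shared variants; child->adult path
# 0.5, no direct childhood effect on the quantitative outcome, adulthood direct
# effect 0.6, hidden confounding 0.3.
seed: 2026
n_variants_child_specific: 20
n_variants_adult_specific: 20
n_variants_shared: 8
effect_sd_child: 0.17
effect_sd_adult: 0.17
gamma_child_to_adult: 0.5
delta_child_direct: 0.0
delta_adult_direct: 0.6
confounder_strength: 0.3
n_exposure_cohort: 5000
n_outcome_cohort: 5000
outcome_kind: quantitative
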