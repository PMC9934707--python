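# Binary-outcome analogue (a T2D-like disease trait, prevalence 10%) with two
# outcome studies meta-analysed on the log-OR scale.
seed: 2027
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
n_outcome_cohort: 8000
outcome_kind: binary
binary_prevalence: 0.1
n_outcome_studies: 2
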