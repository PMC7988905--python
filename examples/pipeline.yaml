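# Full pipeline: simulate -> SES -> inequality -> pooled OR -> decomposition
output_dir: scratch/example_run
input: simulate
alpha: 0.05
decomposition:
  replications: 100
  seed: 7
simulation:
  seed: 42
  countries:
    - name: Alpha
      n_clusters: 80
      children_per_cluster: 60
      rural_cluster_fraction: 0.65
      intercept: -2.0
      rural_effect: 0.4          # structural pro-rural gap (logit scale)
      covariate_effects: {no_education: 0.8, unemployed: 0.3, wealth: -0.15}
      covariate_rural_shift: {no_education: 0.25, wealth: -1.0}
      covariate_base: {no_education: 0.3, unemployed: 0.4}
      covariate_kind: {wealth: ordinal5}
      cluster_sd: 0.25
      weight_cv: 0.25
    - name: Beta
      n_clusters: 80
      children_per_cluster: 60
      rural_cluster_fraction: 0.65
      intercept: -2.0
      rural_effect: 0.0          # compositional gap only
      covariate_effects: {no_education: 0.8, unemployed: 0.3, wealth: -0.15}
      covariate_rural_shift: {no_education: 0.25, wealth: -1.0}
      covariate_base: {no_education: 0.3, unemployed: 0.4}
      covariate_kind: {wealth: ordinal5}
      cluster_sd: 0.25
      weight_cv: 0.25
    - name: Gamma
      n_clusters: 80
      children_per_cluster: 60
      rural_cluster_fraction: 0.65
      intercept: -2.0
      rural_effect: -0.3         # pro-non-rural structural gap
      covariate_effects: {no_education: 0.8, unemployed: 0.3, wealth: -0.15}
      covariate_rural_shift: {no_education: 0.25, wealth: -1.0}
      covariate_base: {no_education: 0.3, unemployed: 0.4}
      covariate_kind: {wealth: ordinal5}
      cluster_sd: 0.25
      weight_cv: 0.25
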