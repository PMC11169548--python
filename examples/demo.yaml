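# Demo pipeline configuration: two synthetic studies, T2D-like conditions.
seed: 7
sim:
  n_individuals: 20000
  n_studies: 2
  beta0: 0.3
  study_sd: 0.05
index_age: 45.0
sexes: [female, male]
bootstrap:
  replicates: 200
model: auto
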