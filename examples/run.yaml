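# Example configuration for `nirs-connectome run-all`.
#
# Every analysis threshold is explicit here with the pipeline's canonical
# defaults; the simulation block is sized for a quick demonstration run
# (a full-scale cohort would use n_channels: 80, duration_s: 480.0,
# n_per_group: 30).
simulation:
  n_channels: 20
  fs: 17.0
  duration_s: 300.0
  n_per_group: 10
  seed: 1
  covariance:
    r_within: 0.35
    r_between: 0.10
    r_homo: 0.30
  effect:
    delta: 0.25
    subject_sd: 0.10
  subject_jitter_sd: 0.03

band: [0.01, 0.1]
segment_s: 240.0
ica_seed: 0
sparsity: 0.2
p_edge: 0.001
n_permutations: 1000
nbs_seed: 0
alpha: 0.05
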