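# Demo scenario: two populations (9 diploids each) that diverged from a
# common ancestor, each with a recent ~10x bottleneck inside the last 30
# generations, plus one outgroup individual for polarization.
seed: 1

simulate:
  mode: linked
  populations:
    - [[0, 500], [30, 5000], [20000, 8000]]
    - [[0, 1000], [25, 10000]]
  split_time_generations: 20000
  mutation_rate: 0.9664e-8
  recombination_rate_cM_per_Mb: 1.0
  generation_time_years: 32
  n_diploids: [9, 9]
  n_chromosomes: 4
  chromosome_length_bp: 10000000
  include_outgroup: true
  outgroup_divergence_generations: 200000

filter:
  enabled: true
  min_genotype_dp: 10
  min_gq: 30
  max_missing_fraction: 0.25
  min_mq: 30
  max_depth_multiplier: 2.0
  min_scaffold_length_bp: 1000000

diversity:
  window_size: 10000

roh:
  method: hmm

stairway:
  enabled: true
  n_boot: 10
  max_steps: 2
  n_restarts: 2

ibdne:
  enabled: true
  min_cM: 2.0
  max_mismatches_per_cM: 1.0
  knots: [4, 6, 9, 13, 19, 28, 42, 63, 95, 140, 200]
  n_boot: 10
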