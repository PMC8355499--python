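# Example study configuration for the `te-longsel` CLI.
#
#   te-longsel run --config examples/study_config.yaml --seed 1 --out runs/demo
#
# Two studies without diets; demographic fields parameterize the drift null.
synthetic:
  n_families: 60
  sigma: 0.3               # coverage noise, insertions per position
  n_positions: 80
  n_s_gt_c: 6              # planted S>C families (+delta copies in S)
  n_c_gt_s: 3
  delta: 1.0
  max_sites_per_family: 100

thresholds:
  alpha: 0.01              # approach #1 Bonferroni level
  delta_min: 0.3           # approach #1 effect-size filter (insertions)
  fdr: 0.05
  site_alpha: 0.05         # per-site Bonferroni level
  window: 1000             # gene-proximity window, bp
  n_sims: 2000             # drift simulations

studies:
  - name: LongTerm
    ne: {C: 150, S: 150}
    generations: {C: 232, S: 146}
    breeding_fraction_selected: 0.5
    populations:
      - {regime: C, replicate: r1, pool_size: 100}
      - {regime: C, replicate: r2, pool_size: 100}
      - {regime: S, replicate: r1, pool_size: 100}
      - {regime: S, replicate: r2, pool_size: 100}
      - {regime: S, replicate: r3, pool_size: 100}
      - {regime: S, replicate: r4, pool_size: 100}
  - name: ShortTerm
    ne: {C: 500, S: 500}
    generations: {C: 70, S: 50}
    populations:
      - {regime: C, replicate: r1, pool_size: 125}
      - {regime: C, replicate: r2, pool_size: 125}
      - {regime: C, replicate: r3, pool_size: 125}
      - {regime: S, replicate: r1, pool_size: 125}
      - {regime: S, replicate: r2, pool_size: 125}
      - {regime: S, replicate: r3, pool_size: 125}
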