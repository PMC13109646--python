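# Simulated swelling-assay cohort: water-injected controls plus two
# channel-expressing constructs, generated from published cohort statistics
# (permeability means/SDs on the 1e-6 cm/s scale, n oocytes per assay).
seed: 42
out_dir: results
adjust: bonferroni
alpha: 0.05
cohort:
  d0_mm: 1.2
  gradient_model: constant
  noise_sd_frac: 1.0e-6
  dt_sample: 30
  duration: 600
  constructs:
    - construct: Control
      water: {n: 26, mean: 1.1, sd: 0.4}
      glycerol: {n: 27, mean: 1.8, sd: 0.6}
      urea: {n: 26, mean: 0.1, sd: 0.4}
    - construct: HpeAqp9
      water: {n: 14, mean: 8.6, sd: 3.5}
      glycerol: {n: 13, mean: 47.1, sd: 21.3}
      urea: {n: 14, mean: 44.5, sd: 14.4}
    - construct: HpeAqp10c1
      water: {n: 9, mean: 11.8, sd: 3.7}
      glycerol: {n: 12, mean: 2.6, sd: 1.0}
      urea: {n: 9, mean: 0.2, sd: 0.2}
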