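# Demo run (~1-2 minutes): two diverged populations with one hard sweep in
# the focal population, analyzed end-to-end (FST/pi cross analysis, iHS,
# xpEHH, candidate regions, annotation, LD decay). Conditions match the
# package's reference sweep-recovery study.
#
#   sweepscan run-all --config configs/demo.yaml
#
focal: pop1
comparisons: [pop2]
seed: 1
out_dir: demo_out
simulate:
  chrom_length: 800000
  n_pops: 2
  pop_size: 300
  split_time: 150
  mu: 8.33e-07         # 4N*mu = 1e-3 per bp
  rec: 3.0e-07         # 4N*rec = 3.6e-4 per bp
  sample_sizes: [50, 50]
  sweep:
    pop: 0             # the focal population
    position: 400000
    s: 0.1
    h: 0.7
    introduction_time: 150
    min_final_freq: 0.9
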