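# Demo: simulate a two-condition proteasome-suppression study and run the
# full pipeline on it.
#   tmabquant all --config examples/demo_config.yaml --out demo_out
seed: 11
simulate:
  n_proteins: 20
  n_peptides_per_protein: 5
  length_range: [6, 30]
  conditions: {control: 2, treated: 3}
  reference: control
  effects: {control: 1.0, treated: 0.35}
  non_product_fraction: 0.1
  cv: 0.15
  tags_per_run: 5
  spectrum:
    mz_jitter_ppm: 2.0
    rt_jitter: 0.02
    lod: 500.0
    n_noise_peaks: 500
    overlap_injection_rate: 0.02
    extra_charge_prob: 0.25
tolerances:
  ppm: 10.0
  rt: 0.2
caps:
  low: 0.20
  high: 5.0
counting_mode: per_replicate
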