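# Small synthetic flyway run: 9 birds, 3 annual cycles.
simulate:
  n_individuals: 9
  n_years: 3
  seed: 11

analysis:
  cluster_radius_km: 250.0
  n_boot: 200
  n_perm: 200
  seed: 11

statistics:
  sensitivity: true
  distance_class_trend: true
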