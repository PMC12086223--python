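# Full-pipeline configuration: synthetic corpus + analysis settings.
synthetic:
  years: [2013, 2014, 2015, 2016, 2017, 2018, 2019, 2020]
  notes_per_year: 2000
  vocab_size: 500
  assoc_schedule: {rho_start: 0.6, rho_end: 0.2}
  seed: 42
analysis:
  base_seeds: [metastatic, mets]
  target_seeds: [palliative, palliation]
  embed_params: {dim: 50, seed: 1}
  n_boot: 10
  boot_seed: 7
  # reviewed concept-family map (the manual-curation step as config)
  assignment:
    metastatic: base
    mets: base
    metastasis: base
    metastasized: base
    widely_metastatic: base
    palliative: target
    palliation: target
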