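# Demo pipeline: phantom -> quantification -> vesicle calls -> exact test.
# Run with: bundlequant run --config examples/demo.yaml
out_dir: demo_run
seed: 5
stages:
  - stage: phantom
    n_cells: 4
    enlarged_fraction: 0.6
  - stage: quantify
    channel: PM
  - stage: vesicles
    diameter_threshold_um: 2.0
  - stage: fisher
    # reference group: 39 of 184 cells flagged (contrast for the phantom's flags)
    reference_counts: [39, 184]
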