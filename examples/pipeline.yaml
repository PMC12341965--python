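# End-to-end pipeline configuration for `synlogic run --config pipeline.yaml`.
# Paths are resolved relative to this file; generate the inputs first with
#   synlogic synthesize --nodes 15 --edges 25 --seed 1 --out system/
network: system/network.sif
calibration: system/steadystate.tab
drug_panel: system/drugpanel.tab
outputs: system/modeloutputs.tab
gold: system/gold.tsv          # optional: enables the benchmark stage
# perturbations: system/perturbations.tab   # optional: defaults to all
seed: 42
out: run/
ga:                            # published schedule; override any field
  population: 20
  generations_max: 20
  selection_count: 3
  mutations_per_model: 3
  burst_multiplier: 1000
  fitness_threshold: 0.99
  evolutions: 50
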