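# One-shot synthetic demo: simulate -> revise -> de -> compare -> annotate.
# Run with:  sporoseq run-all --config configs/demo.yaml
seed: 11
outdir: results/demo
simulate:
  reference:
    n_genes: 200
  counts:
    frac_de: 0.25
  homology:
    core_set_size: 1167
    frac_ortholog: 0.12
de:
  alpha: 0.025
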