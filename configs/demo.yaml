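# Demo end-to-end run: small images and cohorts so the whole pipeline
# (simulate -> correct -> compare -> survival -> metabolomics -> gsea)
# completes in well under five minutes on one CPU.
seed: 1
outdir: dormaflux_demo
n_mice_per_phase: 3
image_size: 128
probe: TMRE
line: fast
phases: [primary, regression]
n_permutations: 1000
n_mice_survival: 30
arms: [control, etomoxir]
recurrence_delta: 0.10
knn_k: 10
n_genes: 2000
geneset_size: 50
expression_effect: 1.0
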