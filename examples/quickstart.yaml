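# Small two-cell-line demonstration run (about a minute on one core).
seed: 11
bins: "-3..3"
simulate:
  n_genes: 200
  decoy_fraction: 0.1
  n_enhancers: 5
  n_cell_lines: 2
  share_weights: false   # cell1 draws its own feature weights
model:
  kind: rf
  n_trees: 100
cv:
  n_repeats: 5
transfer:
  source: cell0
  target: cell1
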