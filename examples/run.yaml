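# Example replication config: one trait with an all-sibling IGE,
# one null trait. Run with:
#   sibige replicate --config examples/run.yaml --out-dir results/demo
n_individuals: 50000
seed: 11
older_sib_only_ige: false
adoption_rate: 0.016
sibling_question_missingness: 0.01
traits:
  - name: ea
    effects: {k_I: 0.5, k_M: 0.1, k_P: 0.1, k_S: 0.2}
  - name: height
    effects: {k_I: 0.6}
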