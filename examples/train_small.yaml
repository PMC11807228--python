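# Desk-scale training configuration: a reduced-width ensemble that runs in
# about a minute on one CPU.  The library defaults (head_dim 256, ten
# members, 300 epochs) match the published full-scale regime.
epochs: 80
batch_size: 16
learning_rate: 0.003
lr_schedule: cosine
n_layers: 3
n_heads: 2
head_dim: 8
mlp_hidden: [32, 16]
seed_list: [0, 1, 2]
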