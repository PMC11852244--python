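# Full-scale geometry (BigBird-base class model, production preset)
n_layers = 12
n_heads = 12
hidden_size = 768
intermediate_size = 3072
block_size = 64
n_random_blocks = 3
n_global_blocks = 2
n_window_blocks = 3
max_positions = 4096
vocab_size = 32000
dropout = 0.1
mlm_mask_rate = 0.15
attention_seed = 0
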