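# Desk-scale geometry for tests and synthetic-genome experiments
n_layers = 2
n_heads = 2
hidden_size = 32
intermediate_size = 128
block_size = 16
n_random_blocks = 1
n_global_blocks = 1
n_window_blocks = 3
max_positions = 256
vocab_size = 512
dropout = 0.1
mlm_mask_rate = 0.15
attention_seed = 0
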