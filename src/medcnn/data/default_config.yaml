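# Pinned default hyperparameters of the methylation classifier.
# Pass to the CLI via --config, or load into ModelConfig(**yaml.safe_load(...)).
encodings: [bpf, ncp, dpcp]
conv_channels: [32, 64]
kernel_size: 5
attention: true
attention_reduction: 8
spatial_kernel_size: 7
embed_dim: 16
fc_width: 128
dropout: 0.3
optimizer: adam
learning_rate: 0.001
batch_size: 64
max_epochs: 100
patience: 10
validation_fraction: 0.1
threshold: 0.5
seed: 0
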