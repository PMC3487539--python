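# Small excitatory-inhibitory network for quick CLI experiments:
#   decorrnet run --config examples/config_small_ei.yaml --out bundle/
scenario: "openloop:poissH"
seed: 1
network: {N: 500, gamma: 0.25, K_E: 40, K_I: 10}
synapse: {kernel: delta, J: 0.4, g: 8.0, delay: 1.0}
drive: {mu_ext: 28.0, sigma_ext: 4.0}
simulation: {duration: 22000.0, warmup: 2000.0, dt: 0.1}
analysis: {bin: 0.5, frame: 1.0, band: [1.0, 10.0], window: 100.0, n_pairs: 2000}
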