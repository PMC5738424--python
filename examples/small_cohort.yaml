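n_nodes: 60
n_patients: 32
n_effectors: 3
seed: 11
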