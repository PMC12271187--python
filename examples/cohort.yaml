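# A small simulated study: QMODE + QMODE+ applications with random
# respiratory rate, contact force, wall target and occasional instability
n_qmode: 40
n_qmode_plus: 8
seed: 2026
p_unstable: 0.08
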