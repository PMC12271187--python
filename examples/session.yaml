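# One QMODE application: stationary contact, 10 breaths/min, 10 s of RF
mode: QMODE
rf_duration_s: 15.0
seed: 1
respiration:
  rate_bpm: 10.0
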