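seed: 7
n_patients: 3
phantom:
  rho_adc:
    edema: 0.25
    ce_tumor: 0.0
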