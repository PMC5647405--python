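species,f_status_quo,f_msy
Cod,0.6,0.19
Haddock,0.17,0.37
Whiting,0.055,0.18
Saithe,0.07,0.32
Mackerel,0.13,0.22
Horse mackerel,0.3,0.13
Herring,0.21,0.16
Hake,0.04,0.27
Anglerfish,0.14,0.19
Blue whiting,0.11,0.3
Norway lobster,0.08,0.116
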