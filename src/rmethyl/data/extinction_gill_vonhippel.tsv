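# Molar extinction coefficients at 280 nm (M^-1 cm^-1), Gill & von Hippel
# (1989) Anal Biochem 182:319-326 / Pace et al. (1995) assay constants.
chromophore	coefficient
Trp	5500
Tyr	1490
cystine	125
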