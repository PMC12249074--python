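# SSDE conversion-factor coefficients: factor(D) = a_e * exp(-b_e * D),
# D = effective diameter in cm.
# body32: AAPM Report 204 (2011), 32 cm phantom exponential fit.
# head16: AAPM Report 293 / TG-293 head analogue for the 16 cm phantom.
source: aapm_rpt204
phantoms:
  body32:
    a_e: 3.704369
    b_e: 0.03671937
  head16:
    a_e: 1.874799
    b_e: 0.03871313
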