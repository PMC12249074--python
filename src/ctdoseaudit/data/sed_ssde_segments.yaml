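# SED-from-SSDE regression segments: SED = a * SSDE - b (a_x_minus_b),
# calibrated per scanned region within a scan-length window.
# source: Martin et al., Monte Carlo SED-SSDE regressions for adult CT.
# The abdomen slope is printed negative (-0.3793) in the source while its
# tabulated percent differences imply the magnitude; the segment ships with
# a = 0.3793 and slope_sign_flipped = true rather than resolving silently.
source: martin_sed_ssde
sign_convention: a_x_minus_b
segments:
  - region: chest
    scan_length_cm: [30.0, 37.0]
    a: 0.5708
    b: 1.2599
  - region: abdomen_pelvis
    scan_length_cm: [40.0, 50.0]
    a: 0.6813
    b: 2.3621
  - region: cap
    scan_length_cm: [62.0, 70.0]
    a: 1.0599
    b: 2.998
  - region: abdomen
    scan_length_cm: [15.0, 30.0]
    a: 0.3793
    b: 1.7078
    slope_sign_flipped: true
  - region: chest_abdomen
    scan_length_cm: [40.0, 50.0]
    a: 0.7798
    b: 0.8491
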