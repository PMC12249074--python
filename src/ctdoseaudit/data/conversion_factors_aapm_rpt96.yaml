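# DLP -> ED conversion factors, mSv per mGy.cm, adult patients.
# source: AAPM Report 96 (2008) k-factor table.
# trunk is not tabulated there; default = mean of chest/abdomen/pelvis,
# overridable.
source: aapm_rpt96
factors:
  head: 0.0021
  neck: 0.0059
  chest: 0.014
  abdomen_pelvis: 0.015
  trunk: 0.014666666666666666
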