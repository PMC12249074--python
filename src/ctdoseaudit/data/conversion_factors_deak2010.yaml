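# DLP -> ED conversion factors, mSv per mGy.cm, adult patients at 120 kV.
# source: Deak, Smal & Kalender, Radiology 257(1):158-166 (2010), ICRP-103
# weighting.  abdomen_pelvis uses the abdomen value; trunk = mean of
# chest/abdomen/pelvis.  Both are overridable.
source: deak2010
factors:
  head: 0.0019
  neck: 0.0051
  chest: 0.0145
  abdomen_pelvis: 0.0153
  trunk: 0.014233333333333334
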