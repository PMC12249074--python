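# Region/scanner-stratified fitted slopes published by a two-scanner
# dose-monitoring audit (y = a*x + b fits of SED vs SSDE and ED vs SSDE),
# together with that cohort's study-level alias counts.  Used as worked-
# example input for the slope-comparison stage; no package logic depends
# on these numbers.
source: published_two_scanner_audit
study_alias_counts:
  head: 22051
  neck: 1378
  chest: 40810
  abdomen: 14541
  pelvis: 603
reported_total_exams: 79383
cells:
  - region: abdomen_pelvis
    scanner: CT1
    sed_slope: 0.747
    sed_intercept: -2.236
    sed_r2: 0.675
    ed_slope: 1.123
    ed_intercept: -7.217
    ed_r2: 0.657
  - region: abdomen_pelvis
    scanner: CT2
    sed_slope: 0.709
    sed_intercept: -1.005
    sed_r2: 0.874
    ed_slope: 0.921
    ed_intercept: -2.8
    ed_r2: 0.936
  - region: chest
    scanner: CT1
    sed_slope: 0.548
    sed_intercept: -0.169
    sed_r2: 0.905
    ed_slope: 0.714
    ed_intercept: -1.031
    ed_r2: 0.85
  - region: chest
    scanner: CT2
    sed_slope: 0.446
    sed_intercept: 0.059
    sed_r2: 0.949
    ed_slope: 0.454
    ed_intercept: 0.0733
    ed_r2: 0.927
  - region: cap
    scanner: CT1
    sed_slope: 0.749
    sed_intercept: 1.092
    sed_r2: 0.759
    ed_slope: 0.935
    ed_intercept: -0.248
    ed_r2: 0.452
  - region: cap
    scanner: CT2
    sed_slope: 0.922
    sed_intercept: -0.58
    sed_r2: 0.913
    ed_slope: 1.182
    ed_intercept: -2.179
    ed_r2: 0.921
  - region: abdomen
    scanner: CT1
    sed_slope: 0.389
    sed_intercept: -0.54
    sed_r2: 0.844
    ed_slope: 0.51
    ed_intercept: -2.116
    ed_r2: 0.827
  - region: chest_abdomen
    scanner: CT1
    sed_slope: 0.717
    sed_intercept: -0.093
    sed_r2: 0.818
    ed_slope: 0.935
    ed_intercept: -2.098
    ed_r2: 0.673
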