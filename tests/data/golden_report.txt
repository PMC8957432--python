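=== cohort concordance summary ===
patients: 2  (node-positive 1.0000)
CT nodes: 6  suspicious: 4 (0.6667)
harvested nodes: 10  metastatic: 3 (0.3000)
overall LNR: 0.3000   overall SPR: 1.33

SPR by station band (suspicious/positive, pooled counts):
   locoregional: 0.67
   intermediate: NA
        central: NA
SPR by tumor site:
             cecum: NA
         ascending: NA
        transverse: NA
        descending: NA
           sigmoid: 1.50
   superior_rectum: 1.00
     middle_rectum: NA
   inferior_rectum: NA
concordance categories (patient-station level):
         positive: 1
         negative: 2
   false_positive: 2
   false_negative: 1

2x2 association, suspicion vs metastasis (plain Pearson)
                                   LNM+                   LNM-    total
      suspicious        2 (2.00) [0.00]        2 (2.00) [0.00]        4
  non-suspicious        1 (1.00) [0.00]        1 (1.00) [0.00]        2
           total                      3                      3        6
chi-square statistic 0.0000, df 1, p 1.00000
node-level   sens 0.667  spec 0.333  PPV 0.500  NPV 0.500
patient-level sens 1.000  spec NA  PPV 1.000  NPV NA

enhancement pattern vs metastasis (one-vs-rest odds of metastasis)
     pattern       OR   CI low   CI high         p  0.5-corr
  homogenous     1.00     0.03     29.81    1.0000     False
      dotted     4.20     0.12    151.97    0.4332      True
      linear     0.24     0.01      8.62    0.4332      True
     central     4.20     0.12    151.97    0.4332      True
  peripheral     0.24     0.01      8.62    0.4332      True
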