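# Default synthetic-cohort configuration (versioned; code loads, never edits).
#
# Two latent classes: "ctd" (CTD-like histology and clinical profile) and
# "idiopathic".  Cohort size, class prevalence, binary covariate rates and
# continuous mean/sd pairs mirror the published validation cohort (94 cases,
# 20 CTD vs 74 idiopathic, four raters).  Class-conditional item score
# distributions are calibrated only to reproduce directions and magnitudes:
# the ctd class weights toward high Plasm/LyGC/AF, the idiopathic class
# toward high FF/SMH/CIP/DPVC/Fat, so the index separates the classes.
n_cases: 94
n_raters: 4
prevalence: 0.2128          # ~20/94
rater_noise_eps: 0.15       # per item per rater, one ordinal step
seed: 20210728
item_dists:                 # P(score = 0,1,2,3) per item per class
  ff:
    ctd: [0.50, 0.30, 0.15, 0.05]
    idiopathic: [0.05, 0.20, 0.45, 0.30]
  smh:
    ctd: [0.50, 0.30, 0.15, 0.05]
    idiopathic: [0.15, 0.35, 0.35, 0.15]
  cip:
    ctd: [0.30, 0.35, 0.25, 0.10]
    idiopathic: [0.30, 0.40, 0.20, 0.10]
  dpvc:
    ctd: [0.50, 0.30, 0.15, 0.05]
    idiopathic: [0.30, 0.40, 0.20, 0.10]
  fat:
    ctd: [0.55, 0.30, 0.10, 0.05]
    idiopathic: [0.40, 0.35, 0.17, 0.08]
  plasm:
    ctd: [0.10, 0.25, 0.35, 0.30]
    idiopathic: [0.55, 0.30, 0.10, 0.05]
  lygc:
    ctd: [0.15, 0.30, 0.30, 0.25]
    idiopathic: [0.60, 0.25, 0.10, 0.05]
  af:
    ctd: [0.45, 0.30, 0.15, 0.10]
    idiopathic: [0.85, 0.10, 0.04, 0.01]
covariate_probs:            # P(positive) per class; sex positive = female,
  sex:                      # smoking positive = ever-smoker
    ctd: 0.75               # 15/20
    idiopathic: 0.2162      # 16/74
  smoking:
    ctd: 0.20               # 4/20
    idiopathic: 0.7162      # 53/74
  ctd_symptom:
    ctd: 0.60               # 12/20
    idiopathic: 0.3378      # 25/74
  ipaf_symptom:
    ctd: 0.25               # 5/20
    idiopathic: 0.1622      # 12/74
  autoantibody:
    ctd: 0.80               # 16/20
    idiopathic: 0.4595      # 34/74
  ipaf_serology:
    ctd: 0.65               # 13/20
    idiopathic: 0.1892      # 14/74
continuous_params:          # [mean, sd] per class
  kl6:
    ctd: [1438.0, 1019.0]
    idiopathic: [1830.0, 2433.0]
  spd:
    ctd: [321.6, 235.9]
    idiopathic: [297.6, 199.3]
  pao2:
    ctd: [83.4, 14.8]
    idiopathic: [81.0, 14.6]
  paco2:
    ctd: [43.5, 10.5]
    idiopathic: [41.7, 8.91]
  spo2_low:
    ctd: [88.0, 5.14]
    idiopathic: [84.8, 8.81]
  fvc_pct:
    ctd: [82.1, 19.0]
    idiopathic: [86.5, 16.7]
  dlco_pct:
    ctd: [69.4, 13.9]
    idiopathic: [73.2, 45.2]
  bal_total:
    ctd: [2.71, 3.4]
    idiopathic: [2.02, 1.3]
  bal_mac:
    ctd: [74.2, 22.6]
    idiopathic: [75.1, 24.7]
  bal_ly:
    ctd: [15.13, 18.1]
    idiopathic: [11.3, 15.3]
  bal_neut:
    ctd: [5.74, 12.8]
    idiopathic: [8.09, 13.1]
  bal_eo:
    ctd: [3.66, 3.8]
    idiopathic: [3.32, 6.99]
  cd4_8:
    ctd: [1.49, 1.33]
    idiopathic: [2.89, 2.36]
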