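# Illustrative disturbance-demography coefficient set.
#
# These are NOT the published national beta-regression estimates (those
# coefficients and precisions are distributed by their authors on request
# and are not reproduced here).  This set has the same structure — survival
# and recruitment declining with buffered anthropogenic disturbance, wide
# among-population variation — with S ~ 0.87 and R ~ 30 calves per 100 cows
# at zero disturbance.  Replace with transcribed values for real analyses.
model_id_survival: M4
model_id_recruitment: M1
survival:
  link: logit
  intercept: 1.95
  coef_anthro: -0.020
  coef_fire: 0.0
  precision: 65.0
recruitment:
  link: log
  intercept: 3.40        # exp(3.40) ~ 30 calves per 100 cows at zero disturbance
  coef_anthro: -0.011
  coef_fire: -0.002
  precision: 18.0
  scale: 100.0           # calibrated in calves per 100 cows
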