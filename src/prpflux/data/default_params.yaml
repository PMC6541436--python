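# Calibrated default rate constants (1/min).
# Generated by scripts/fit_defaults.py -- do not edit by hand.
calibration:
  targets:
    lag_min: 30.0
    degraded_180min: 0.8
    basal_surface_fraction: 0.044
    slope_ratio_30_90: 6.0
  fitted:
    lag_min: 12.500794182947663
    degraded_180min: 0.8000000000000015
    basal_surface_fraction: 0.044000000000000004
    slope_ratio_30_90: 6.00000000000001
  stress_basal_exit_ratio: 16.67111576419398
  note: lag is the closest the first-order chain can come to the 30 min target once
    80% degradation at 180 min is imposed; see docs/methods.md
stress:
  k_exit: 0.023323182853381388
  k_gp: 0.02223009569218283
  k_endo: 0.02823630883877332
  k_deg: 0.10300227743484865
basal:
  k_exit: 0.00139901750928241
  k_gp: 0.02223009569218283
  k_endo: 0.02823630883877332
  k_deg: 0.10300227743484865
wt:
  k_exit: 0.2
  k_gp: 0.2
  k_endo: 0.0024904214559386974
  k_deg: 0.02
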