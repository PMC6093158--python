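{
  "description": "Published posterior summary of the persistence-colonization range-change model for sika deer (1978 -> 2003, n = 15,256 cells). Columns: mean, sd, quantiles (2.5/25/50/75/97.5%), Rhat. phi_* parameterise logit(persistence) = phi0 + phi_d*D + phi_h*H; gam_* parameterise logit(colonization) = gam0 + gam_d*D + gam_h*H, with D the neighborhood occupancy and H the habitat suitability (log-odds).",
  "parameters": {
    "phi0":  {"mean": -0.04, "sd": 0.17, "q2.5": -0.36, "q25": -0.15, "q50": -0.04, "q75": 0.07, "q97.5": 0.31, "rhat": 1.00},
    "phi_d": {"mean": 5.95, "sd": 0.34, "q2.5": 5.26, "q25": 5.72, "q50": 5.94, "q75": 6.17, "q97.5": 6.62, "rhat": 1.00},
    "phi_h": {"mean": 0.50, "sd": 0.06, "q2.5": 0.38, "q25": 0.46, "q50": 0.50, "q75": 0.54, "q97.5": 0.63, "rhat": 1.00},
    "gam0":  {"mean": -1.34, "sd": 0.05, "q2.5": -1.43, "q25": -1.37, "q50": -1.34, "q75": -1.31, "q97.5": -1.25, "rhat": 1.00},
    "gam_d": {"mean": 8.29, "sd": 0.20, "q2.5": 7.90, "q25": 8.15, "q50": 8.28, "q75": 8.42, "q97.5": 8.69, "rhat": 1.00},
    "gam_h": {"mean": 0.64, "sd": 0.02, "q2.5": 0.60, "q25": 0.63, "q50": 0.64, "q75": 0.66, "q97.5": 0.68, "rhat": 1.00}
  },
  "deviance": {"mean": 10018.92, "sd": 7.06, "q2.5": 10010, "q50": 10020, "q97.5": 10030},
  "waic_per_obs_best": 0.3288,
  "auc_best": 0.9334,
  "threshold": 0.1725,
  "best_dispersal": {"radius_km": 100, "weight_exponent": 2},
  "best_surface_epoch": 2003
}
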