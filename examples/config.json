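{
  "population": {
    "n_total": 20000,
    "prevalence_eligible": 0.05,
    "mean_degree": 7,
    "degree_dispersion": 1.5,
    "degree_max": 99,
    "homophily": {"zone": 0.3},
    "rng_seed": 42
  },
  "simulation": {
    "n_seeds": 12,
    "coupons_per_participant": 3,
    "participation_prob": {"low": 0.0, "high": 0.65},
    "incentive_schedule": {"0": "low", "60": "high"},
    "target_n": 330,
    "horizon_days": 300,
    "rng_seed": 42
  },
  "intake": {
    "similarity_threshold": 0.2,
    "dob_window_days": 1
  },
  "analysis": {
    "convergence_variables": ["age_group", "sex"],
    "estimate_variables": ["sex"],
    "window_frac": 0.25,
    "tol": 0.02
  }
}
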