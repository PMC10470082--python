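{
  "name": "sf6d-hk-synthetic",
  "comment": "SYNTHETIC stand-in for the Hong Kong SF-6Dv1 value set. Same dimension structure (6/4/5/6/5/5 levels, 18,000 states), additive, anchored at 1 for full health, floor 0.315 at the all-worst state, next-feasible value below full health 0.965. The level decrements themselves are invented (monotone, plausible magnitudes); they are NOT the published Hong Kong coefficients.",
  "constant": 1.0,
  "dimensions": [
    {"name": "pf",   "levels": 6, "decrements": [0.0, -0.040, -0.055, -0.075, -0.105, -0.150]},
    {"name": "rl",   "levels": 4, "decrements": [0.0, -0.035, -0.055, -0.080]},
    {"name": "sf",   "levels": 5, "decrements": [0.0, -0.040, -0.060, -0.085, -0.110]},
    {"name": "pain", "levels": 6, "decrements": [0.0, -0.038, -0.060, -0.090, -0.120, -0.155]},
    {"name": "mh",   "levels": 5, "decrements": [0.0, -0.040, -0.062, -0.088, -0.110]},
    {"name": "vit",  "levels": 5, "decrements": [0.0, -0.036, -0.052, -0.068, -0.080]}
  ],
  "global_terms": [],
  "floor": 0.315
}
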