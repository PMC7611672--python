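# Default hierarchical priors for the ex-Gaussian race model.
#
# Group-level location priors are truncated normals; group-level scale
# priors are truncated normals centred at scale_loc (half-normal-like).
# Failure probabilities are modelled on the probit scale (z_tf, z_gf with
# p = Phi(z)).  The location-prior means of 1.5 s for the two go runners'
# mu and 1.0 s for mu_stop follow the convention of allowing for slower
# responses in older participants; every other number here is a
# weakly-informative implementation default of this package.
version: 1
parameters:
  mu_go_match:      {loc_mean: 1.5,  loc_sd: 1.0, lower: 0.001, upper: 10.0, scale_loc: 0.0, scale_sd: 1.0, scale_lower: 0.005, scale_upper: 5.0}
  sigma_go_match:   {loc_mean: 0.2,  loc_sd: 1.0, lower: 0.001, upper: 5.0,  scale_loc: 0.0, scale_sd: 0.5, scale_lower: 0.005, scale_upper: 3.0}
  tau_go_match:     {loc_mean: 0.2,  loc_sd: 1.0, lower: 0.001, upper: 5.0,  scale_loc: 0.0, scale_sd: 0.5, scale_lower: 0.005, scale_upper: 3.0}
  mu_go_mismatch:   {loc_mean: 1.5,  loc_sd: 1.0, lower: 0.001, upper: 10.0, scale_loc: 0.0, scale_sd: 1.0, scale_lower: 0.005, scale_upper: 5.0}
  sigma_go_mismatch: {loc_mean: 0.2, loc_sd: 1.0, lower: 0.001, upper: 5.0,  scale_loc: 0.0, scale_sd: 0.5, scale_lower: 0.005, scale_upper: 3.0}
  tau_go_mismatch:  {loc_mean: 0.2,  loc_sd: 1.0, lower: 0.001, upper: 5.0,  scale_loc: 0.0, scale_sd: 0.5, scale_lower: 0.005, scale_upper: 3.0}
  mu_stop:          {loc_mean: 1.0,  loc_sd: 1.0, lower: 0.001, upper: 10.0, scale_loc: 0.0, scale_sd: 1.0, scale_lower: 0.005, scale_upper: 5.0}
  sigma_stop:       {loc_mean: 0.15, loc_sd: 1.0, lower: 0.001, upper: 5.0,  scale_loc: 0.0, scale_sd: 0.5, scale_lower: 0.005, scale_upper: 3.0}
  tau_stop:         {loc_mean: 0.15, loc_sd: 1.0, lower: 0.001, upper: 5.0,  scale_loc: 0.0, scale_sd: 0.5, scale_lower: 0.005, scale_upper: 3.0}
  z_tf:             {loc_mean: -1.5, loc_sd: 1.0, lower: -6.0,  upper: 6.0,  scale_loc: 0.0, scale_sd: 1.0, scale_lower: 0.01,  scale_upper: 3.0}
  z_gf:             {loc_mean: -1.5, loc_sd: 1.0, lower: -6.0,  upper: 6.0,  scale_loc: 0.0, scale_sd: 1.0, scale_lower: 0.01,  scale_upper: 3.0}
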