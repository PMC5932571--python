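{
  "framework_version": "gill-uptake-kinetic-2004.1",
  "gill_uptake_a": 1.85,
  "gill_uptake_b": 155.0,
  "ventilation_coeff_l_per_day": 1400.0,
  "ventilation_weight_exponent": 0.65,
  "oxygen_temp_slope": -0.24,
  "oxygen_temp_intercept": 14.04,
  "oxygen_saturation": 0.9
}
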