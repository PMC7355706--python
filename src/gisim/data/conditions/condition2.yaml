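# Condition 2: 250 mL tap water + 50 mL FaSSGF, gastric emptying t1/2 30 min.
label: condition2
t_half_gastric: 30.0
gastric_initial_volume: 300.0
gastric_residual_floor: 5.0
duodenal_volume: 50.0
jejunal_initial_volume: 0.0
k_sec_s: 1.0
k_sec_d: 1.0
duration: 60.0
gastric_ph_profile: [[0.0, 2.0], [60.0, 2.0]]
duodenal_ph_profile: [[0.0, 6.5], [60.0, 6.5]]
jejunal_ph_profile: [[0.0, 6.5], [60.0, 6.5]]
transit_parameters:
  z_s: 1.72e-11
  z_d: 3.63e-11
  z_j: 6.11e-12
  frac: 0.844
  k_pre_d: 0.155
  k_pre_j: 2.73e-3
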