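# Condition 4: 250 mL Coca-Cola + 50 mL FaSSGF, gastric emptying t1/2 30 min.
# Slower emptying halves the acid load rate: the duodenal dip is shallower
# (observed minimum pH 4.25, placed at 15 min, recovery to 6.5 by 60 min).
label: condition4
t_half_gastric: 30.0
gastric_initial_volume: 300.0
gastric_residual_floor: 5.0
duodenal_volume: 50.0
jejunal_initial_volume: 0.0
k_sec_s: 1.0
k_sec_d: 1.0
duration: 60.0
gastric_ph_profile: [[0.0, 2.48], [60.0, 2.48]]
duodenal_ph_profile: [[0.0, 6.5], [15.0, 4.25], [60.0, 6.5]]
jejunal_ph_profile: [[0.0, 6.5], [60.0, 6.5]]
transit_parameters:
  z_s: 7.41e-11
  z_d: 5.31e-11
  z_j: 6.11e-12
  frac: 0.628
  k_pre_d: 5.75e-10
  k_pre_j: 1.90e-5
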