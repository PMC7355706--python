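# Condition 3: 250 mL Coca-Cola + 50 mL FaSSGF, gastric emptying t1/2 15 min.
# Gastric pH constant at the cola value; the acidic load drives a transient
# duodenal pH dip to the observed minimum of 3.27 (timing of the minimum is
# not published; placed at 15 min with recovery to 6.5 by 60 min).
label: condition3
t_half_gastric: 15.0
gastric_initial_volume: 300.0
gastric_residual_floor: 5.0
duodenal_volume: 50.0
jejunal_initial_volume: 0.0
k_sec_s: 1.0
k_sec_d: 1.0
duration: 60.0
gastric_ph_profile: [[0.0, 2.48], [60.0, 2.48]]
duodenal_ph_profile: [[0.0, 6.5], [15.0, 3.27], [60.0, 6.5]]
jejunal_ph_profile: [[0.0, 6.5], [60.0, 6.5]]
transit_parameters:
  z_s: 1.51e-10
  z_d: 3.63e-11
  z_j: 6.11e-12
  frac: 0.296
  k_pre_d: 1.38e-5
  k_pre_j: 1.90e-5
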