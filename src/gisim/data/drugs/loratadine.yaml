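# Loratadine, 10 mg immediate-release tablet (generic).
# pKa/logP from the experimentally grounded literature pair (Stillhart et al.);
# the intrinsic solubility of the neutral species is not tabulated in the
# source study: s0_ug_per_ml is a documented calibration constant in the
# literature low-µg/mL range for neutral loratadine, set (jointly with the
# package z-factor unit scale) so the condition-1 pipeline reproduces the
# published simulated exposure, and held fixed across all four conditions.
name: loratadine
dose_mg: 10
pka: 5.3
logp: 3.9
mw: 382.89
s0_ug_per_ml: 3.0
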