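# Alternative loratadine property set using in-silico predicted constants
# (basic pKa 3.83, cLogP 4.54) rather than the measured literature pair.
# Kept as a named preset because both values circulate for this compound;
# the default preset (loratadine.yaml) uses the measured pair.
name: loratadine_admet
dose_mg: 10
pka: 3.83
logp: 4.54
mw: 382.89
s0_ug_per_ml: 3.0
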