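{
 "C_m": 20.0,
 "g_leak": 1.0,
 "E_leak": -40.0,
 "g_K": 40.0,
 "E_K": -90.0,
 "n_vhalf": -25.0,
 "n_slope": 9.0,
 "tau_n": 4.0,
 "g_adapt": 3.0,
 "tau_z": 100.0,
 "z_inc": 0.35,
 "spike_thresh": -20.0,
 "E_Na": 60.0,
 "V_init": -65.0
}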