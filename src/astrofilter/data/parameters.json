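{
  "_comment": "G-ChI astrocyte kinetics (FM-encoding regime), nonlinear GJC coupling and Tsodyks-Markram equivalent synapse. Concentrations in uM, time in s. Rate constants derive from the published G-ChI FM-regime values with a uniform kinetic scaling plus targeted adjustments (SERCA affinity, IP3R inactivation rate, PLCbeta rate, PLCdelta rate) calibrated so that (i) a strongly driven isolated astrocyte oscillates at ~0.2 Hz maximal frequency, (ii) the single-cell onset of responsiveness sits near 2 Hz, (iii) directly stimulated cells initiate their response within ~1.5 s at high stimulation frequency, and (iv) PLCdelta is low enough to suppress regenerative intercellular waves.",
  "r_c": {"value": 20.7, "units": "1/s"},
  "r_l": {"value": 0.3795, "units": "1/s"},
  "v_er": {"value": 3.105, "units": "uM/s"},
  "k_er": {"value": 0.05, "units": "uM"},
  "c_tot": {"value": 2.0, "units": "uM"},
  "rho_er": {"value": 0.185, "units": "1"},
  "d1": {"value": 0.13, "units": "uM"},
  "d2": {"value": 1.049, "units": "uM"},
  "d3": {"value": 0.9434, "units": "uM"},
  "d5": {"value": 0.078, "units": "uM"},
  "o2": {"value": 0.276, "units": "1/(uM s)"},
  "o_beta": {"value": 2.6, "units": "uM/s"},
  "k_r": {"value": 1.3, "units": "uM"},
  "k_p": {"value": 10.0, "units": "uM"},
  "k_pi": {"value": 0.6, "units": "uM"},
  "n_glu": {"value": 0.7, "units": "1"},
  "o_delta": {"value": 0.01725, "units": "uM/s"},
  "kappa_delta": {"value": 1.5, "units": "uM"},
  "k_delta": {"value": 0.1, "units": "uM"},
  "o_3k": {"value": 6.9, "units": "uM/s"},
  "k_d": {"value": 0.7, "units": "uM"},
  "k_3": {"value": 1.0, "units": "uM"},
  "omega_5p": {"value": 0.138, "units": "1/s"},
  "f_gjc": {"value": 3.0, "units": "uM/s"},
  "i_theta": {"value": 0.15, "units": "uM"},
  "omega_i": {"value": 0.05, "units": "uM"},
  "u0": {"value": 0.6, "units": "1"},
  "omega_f": {"value": 2.0, "units": "1/s"},
  "omega_d": {"value": 40.0, "units": "1/s"},
  "omega_c": {"value": 6.0, "units": "1/s"},
  "g_release": {"value": 0.09, "units": "uM"}
}
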