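# Closed-loop 0D cardiovascular model constants.
#
# Transcription of the lumped-parameter circulation with carotid baroreflex
# of Ursino, Am J Physiol 274 (1998) H1733-H1747, the source model this
# simulator re-implements.  Units: pressures mmHg, volumes ml, flows ml/s,
# resistances mmHg.s/ml, compliances ml/mmHg, inertances mmHg.s^2/ml,
# times s, neural firing rates spikes/s.
#
# version: 1 (see docs/methods.md for field-by-field notes)

circulation:
  total_volume: 5300.0
  systemic_arteries:   {C: 0.28,  V0: 0.0,    R: 0.06,   L: 2.2e-4}
  splanchnic_peripheral:      {C: 2.05,  V0: 274.4}
  extrasplanchnic_peripheral: {C: 1.67,  V0: 134.64}
  # venous unstressed volumes are baroreflex effectors (theta0 below);
  # the values here are the basal (with sympathetic tone) operating values
  splanchnic_venous:          {C: 61.11, R: 0.038, V0_basal: 1121.0}
  extrasplanchnic_venous:     {C: 50.0,  R: 0.016, V0_basal: 1375.0}
  pulmonary_arteries:  {C: 0.76,  V0: 0.0,   R: 0.023,  L: 1.8e-4}
  pulmonary_peripheral: {C: 5.8,  V0: 123.0, R: 0.0894}
  pulmonary_veins:     {C: 25.37, V0: 120.0, R: 0.0056}

heart:
  left_atrium:  {C: 19.23, V0: 25.0, R: 2.5e-3}
  right_atrium: {C: 31.25, V0: 25.0, R: 2.5e-3}
  # ventricles: P_passive = P0*(exp(kE*V) - 1); viscous loss R = kR * P_max
  left_ventricle:  {P0: 1.5, kE: 0.014, V0: 16.77, kR: 3.75e-4}
  right_ventricle: {P0: 1.5, kE: 0.011, V0: 40.8,  kR: 1.4e-3}
  # systolic duration Tsys = Tsys0 - ksys / T;  T0 = unregulated heart period
  timing: {Tsys0: 0.5, ksys: 0.075, T0: 0.58}

baroreflex:
  # carotid afferent: first-order filter of P_sa + tau_zp * dP_sa/dt,
  # then sigmoidal firing f_cs
  afferent:
    tau_p: 2.076
    tau_zp: 6.37
    f_min: 2.52
    f_max: 47.78
    P_n: 92.0
    k_a: 11.758
  # efferent static characteristics
  efferent:
    f_es_inf: 2.10
    f_es_0: 16.11
    k_es: 0.0675
    f_es_min: 2.66
    f_ev_0: 3.2
    f_ev_inf: 6.3
    f_cs_0: 25.0
    k_ev: 7.06
  # effectors: theta(t) = theta0 + x, dx/dt = (sigma - x)/tau,
  # sigma = gain * ln(f_es(t - delay) - f_es_min + 1)  (sympathetic)
  # heart-period vagal branch uses sigma = gain * f_ev(t - delay)
  effectors:
    emax_lv: {tau: 8.0, delay: 2.0}          # gain & theta0 are HF parameters
    emax_rv: {gain: 0.282, tau: 8.0, delay: 2.0, theta0: 1.412}
    r_sp:    {gain: 0.695, tau: 6.0, delay: 2.0, theta0: 2.49}
    r_ep:    {gain: 0.2957, tau: 6.0, delay: 2.0, theta0: 1.081}
    vu_sv:   {gain: -265.4, tau: 20.0, delay: 5.0, theta0: 1435.4}
    vu_ev:   {gain: -132.5, tau: 20.0, delay: 5.0, theta0: 1537.0}
    t_sym:   {gain: -0.13, tau: 2.0, delay: 2.0}
    t_vag:   {gain: 0.09, tau: 1.5, delay: 0.2}

# heart-failure parameter sampling ranges (uniform, independent);
# defaults are the empirical min/max of the study population
hf_ranges:
  Emax_lv:  [0.200, 2.95]
  Emax_lv0: [0.200, 2.39]
  G_Emaxlv: [0.200, 0.475]
  kE_lv:    [0.0110, 0.0140]

# healthy reference point (no failure)
hf_healthy: {Emax_lv: 2.95, Emax_lv0: 2.392, G_Emaxlv: 0.475, kE_lv: 0.014}

solver:
  dt_max: 5.0e-4        # fixed RK4 step upper bound, s
  volume_tol: 1.0e-3    # relative blood-volume conservation tolerance

# nominal pressures used to distribute the initial blood volume
init_pressures: {sa: 90.0, sp: 85.0, ep: 85.0, pa: 15.0, pp: 10.0, pv: 6.0,
                 la: 5.0, ra: 3.0}
init_volumes: {lv: 120.0, rv: 120.0}
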