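# Default biophysical parameter set, version 1.
#
# Two-compartment (soma + dendrite) conductance-based motor neuron of the
# Booth-Rinzel-Kiehn lineage, extended with a persistent sodium current and a
# recurrent Renshaw-cell network.  Conductances in mS/cm^2, voltages in mV,
# capacitance in uF/cm^2, time constants in ms, calcium in uM.
#
# Calcium pools follow first-order kinetics: influx proportional to the
# respective calcium current (factor alpha), first-order removal (rate k_ca),
# both scaled by the fraction f of free calcium.
#
# Gate kinetics: steady state w_inf(V) = 1 / (1 + exp((V - theta) / k)).
# tau is a constant time constant in ms; tau: 0.0 marks an instantaneous gate
# (w = w_inf(V) at every step).  The sodium inactivation (h) and delayed
# rectifier activation (n) gates use a voltage-dependent time constant
# tau(V) = tau_scale / (exp((V - tau_theta)/tau_k1) + exp(-(V - tau_theta)/tau_k2)).

meta:
  version: 1

motor_neuron:
  membrane:
    C_m: 1.0          # uF/cm^2
    p: 0.1            # soma / total area ratio
    g_c: 0.1          # soma-dendrite coupling, mS/cm^2
    g_L: 0.51         # leak, both compartments
    V_L: -60.0
  reversal:
    V_Na: 55.0
    V_K: -80.0
    V_Ca: 80.0
    V_excit: 0.0      # excitatory synaptic reversal (drive port)
    V_inhib: -75.0    # Renshaw inhibition reversal
  soma:
    g_Na: 120.0
    g_K_dr: 100.0
    g_Ca_N: 14.0
    g_K_Ca: 20.0      # slow AHP; sets the 7-13 Hz tonic range
    g_NaP: 0.1
  dendrite:
    g_Ca_N: 0.3
    g_Ca_L: 0.1
    g_K_Ca: 0.7
  calcium:
    f: 0.01           # free-calcium fraction
    alpha: 0.009      # influx per unit Ca current, uM cm^2 / (ms uA)
    k_ca: 2.0         # removal rate, 1/ms (scaled by f)
    K_d: 0.2          # K(Ca) half-saturation, uM
  gates:
    m:   {theta: -35.0, k: -7.8, tau: 0.0}        # Na activation, instantaneous
    h:   {theta: -55.0, k: 7.0,
          tau_scale: 30.0, tau_theta: -50.0, tau_k1: 15.0, tau_k2: 16.0}
    n:   {theta: -28.0, k: -15.0,
          tau_scale: 7.0, tau_theta: -40.0, tau_k1: 40.0, tau_k2: 50.0}
    m_N: {theta: -30.0, k: -5.0, tau: 4.0}        # N-type Ca activation
    h_N: {theta: -45.0, k: 5.0, tau: 40.0}        # N-type Ca inactivation
    m_L: {theta: -40.0, k: -7.0, tau: 40.0}       # L-type Ca activation (dendrite)
    m_P: {theta: -50.0, k: -5.0, tau: 0.0}        # persistent Na activation
    h_P: {theta: -60.0, k: 6.0, tau: 1000.0}      # persistent Na slow inactivation
  spike_detection:
    threshold: 0.0    # mV, upward crossing on V_S
    lockout_ms: 2.0
  drive:
    # Independent input m_II(t) = C_j + noise_scale * sqrt(C_j) * xi(t), one
    # Gaussian sample per integration step per MN, applied as dendritic
    # excitatory conductance.  At the default noise_scale of 1 the noise SD
    # is exactly sqrt(C_j); the calibrated pool then fires at an
    # interspike-interval CoV of ~0.2, with window-rate CoV far below the
    # 0.3 exclusion bound.  See docs/methods.md.
    noise_scale: 1.0

renshaw:
  count: 64
  in_degree_mn: 50    # MNs driving each RC
  out_degree_rc: 20   # RCs inhibiting each MN
  membrane:
    C_m: 1.0
    g_Na: 120.0
    g_K: 36.0
    g_L: 0.3
    V_L: -65.0
    V_Na: 55.0
    V_K: -80.0
  gates:
    m: {theta: -35.0, k: -7.8, tau: 0.0}
    h: {theta: -55.0, k: 7.0,
        tau_scale: 30.0, tau_theta: -50.0, tau_k1: 15.0, tau_k2: 16.0}
    n: {theta: -28.0, k: -15.0,
        tau_scale: 7.0, tau_theta: -40.0, tau_k1: 40.0, tau_k2: 50.0}
  adaptation:
    g_step: 1.9       # AHP conductance increment per RC spike, mS/cm^2
                      # tuned once so the RC baseline rate is ~11 spikes/s
                      # in the calibrated no-CI pool
    tau: 60.0         # decay, ms
  synapse:
    w_mn_rc: 0.15     # MN spike -> RC excitatory conductance step, mS/cm^2
    tau_mn_rc: 2.0    # ms
    V_syn_rc: 0.0
    w_rc_mn: 0.004    # RC spike -> MN dendritic inhibitory conductance step
    tau_rc_mn: 10.0   # ms
  spike_detection:
    threshold: 0.0
    lockout_ms: 2.0

force:
  # Twitch: critically damped impulse response A * (t/T) * exp(1 - t/T);
  # ISI-dependent sigmoidal gain of the Fuglevand type (unity below
  # normalised rate 0.4).  Twitch amplitudes follow the field's standard
  # exponential spread across the pool (here a 10-fold range, appropriate
  # for a slow-type-only pool); larger units twitch faster via a power law,
  # T = ct_max * A^(-ct_exponent) (110 ms down to ~62 ms).
  amp_min: 1.0
  amp_max: 10.0
  ct_max_ms: 110.0
  ct_exponent: 0.25
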