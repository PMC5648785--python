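# Default parameter set of the four-population thalamocortical mean-field
# model (pyramidal PY and interneuron IN cortical populations;
# thalamocortical relay TC and reticular RE thalamic populations), in the
# lineage of the lumped bistable thalamocortical network of Suffczynski,
# Kalitzin & Lopes da Silva (2004), Neuroscience 126:467-484.
#
# Units: time s, potentials mV, capacitance uF, conductance uS, firing
# densities pps (pulses per second); rate constants 1/s; couplings are
# dimensionless mean synaptic-contact counts.
#
# Provenance: wiring, equation structure and kinetic time constants follow
# the published description of that model family and standard values for
# AMPA / GABA_A / GABA_B kinetics and low-threshold burst gating; synaptic
# amplitudes and contact counts are this package's own calibration, fixed
# once so the network reproduces the documented operating regime of the
# original network: a stable low-activity equilibrium coexisting with a
# large-amplitude ~9-10 Hz paroxysmal limit cycle around the nominal
# operating biases (cortical 13.5 pps, sensory 11 pps, reticular 12 pps),
# with an abrupt resonant transition onto the paroxysmal branch when the
# cortical drive frequency approaches the paroxysmal rhythm.  Thalamic
# firing is tonic + burst (the two modes sum); cortical firing is tonic
# only.  Inter-module conduction delays are supported by the loader but
# set to zero here (absorbed into the synaptic rise times).
#
# The analysis pipeline accepts any parameter file with this schema; no
# test of the property suite depends on the numbers below.

name: thalamocortical-default
version: 1

populations:
  # C_m uF; g_leak uS (tau_m = C_m/g_leak = 20 ms); V_leak mV;
  # tonic sigmoid: max rate G_F pps, threshold theta_F mV, slope nu_F 1/mV
  # (negative slope: firing grows with depolarisation)
  PY: {C_m: 1.0, g_leak: 50.0, V_leak: -64.0, G_F: 50.0, theta_F: -55.0, nu_F: -0.4}
  IN: {C_m: 1.0, g_leak: 50.0, V_leak: -64.0, G_F: 50.0, theta_F: -55.0, nu_F: -0.4}
  TC: {C_m: 1.0, g_leak: 50.0, V_leak: -65.0, G_F: 30.0, theta_F: -45.0, nu_F: -0.5}
  RE: {C_m: 1.0, g_leak: 50.0, V_leak: -70.0, G_F: 60.0, theta_F: -50.0, nu_F: -0.5}

synapses:
  # bi-exponential kernels, unit DC gain A*(1/a1 - 1/a2) = 1 uS per pps
  # except where noted; a1 = decay rate, a2 = rise rate (1/s, a2 > a1)
  PY.AMPA:   {A: 225.0,   a1: 180.0,  a2: 900.0,  V_rev: 0.0,    syn_type: AMPA}
  PY.GABA_A: {A: 111.11,  a1: 100.0,  a2: 1000.0, V_rev: -85.0,  syn_type: GABA_A}
  PY.GABA_B: {A: 12.5,    a1: 10.0,   a2: 50.0,   V_rev: -100.0, syn_type: GABA_B}
  IN.AMPA:   {A: 225.0,   a1: 180.0,  a2: 900.0,  V_rev: 0.0,    syn_type: AMPA}
  TC.AMPA:   {A: 225.0,   a1: 180.0,  a2: 900.0,  V_rev: 0.0,    syn_type: AMPA}
  # slower intra-thalamic GABA_A decay (~25 ms) paces the paroxysmal rhythm
  TC.GABA_A: {A: 42.808,  a1: 39.957, a2: 600.0,  V_rev: -85.0,  syn_type: GABA_A}
  TC.GABA_B: {A: 12.5,    a1: 10.0,   a2: 50.0,   V_rev: -100.0, syn_type: GABA_B}
  RE.AMPA:   {A: 225.0,   a1: 180.0,  a2: 900.0,  V_rev: 0.0,    syn_type: AMPA}
  RE.GABA_A: {A: 111.11,  a1: 100.0,  a2: 1000.0, V_rev: -85.0,  syn_type: GABA_A}

# c1-c13: directed pathways (mean synaptic-contact counts). External
# drives enter through the same kernel machinery: sensory -> TC (AMPA),
# cortical -> PY (AMPA), reticular -> RE (GABA_A: the inhibitory bias
# from neighbouring reticular sectors).  'delayed: true' marks the
# inter-module pathways subject to the conduction delays in 'network'.
couplings:
  c1:  {source: sensory,   target: TC, syn_type: AMPA,   value: 1.6}
  c2:  {source: cortical,  target: PY, syn_type: AMPA,   value: 2.3}
  c3:  {source: reticular, target: RE, syn_type: GABA_A, value: 4.8736}
  c4:  {source: PY, target: IN, syn_type: AMPA,   value: 2.7066}
  c5:  {source: IN, target: PY, syn_type: GABA_A, value: 3.0}
  c6:  {source: IN, target: PY, syn_type: GABA_B, value: 0.3}
  c7:  {source: TC, target: PY, syn_type: AMPA,   value: 4.0, delayed: true}
  c8:  {source: TC, target: IN, syn_type: AMPA,   value: 1.0, delayed: true}
  c9:  {source: PY, target: TC, syn_type: AMPA,   value: 0.5, delayed: true}
  c10: {source: PY, target: RE, syn_type: AMPA,   value: 0.5, delayed: true}
  c11: {source: TC, target: RE, syn_type: AMPA,   value: 2.734}
  c12: {source: RE, target: TC, syn_type: GABA_A, value: 4.6293}
  c13: {source: RE, target: TC, syn_type: GABA_B, value: 3.311}

gabab_activation:
  # sigmoidal recruitment of the slow inhibition by presynaptic rate:
  # engaged only by strong (burst-mode) firing
  TC: {theta_B: 20.0, nu_B: -0.5}
  PY: {theta_B: 20.0, nu_B: -0.5}

burst:
  # low-threshold burst mode: G_B pps; h_n kernel decay n1 / rise n2 (1/s);
  # activation gate m_inf (opens with depolarisation), availability gate
  # n_inf (de-inactivates with hyperpolarisation)
  TC: {G_B: 300.0, n1: 20.0, n2: 80.0, theta_m: -60.0, nu_m: -1.0, theta_n: -70.0, nu_n: 0.5}
  RE: {G_B: 300.0, n1: 20.0, n2: 80.0, theta_m: -60.0, nu_m: -1.0, theta_n: -70.0, nu_n: 0.5}

network:
  delay_cortex_to_thalamus: 0.0
  delay_thalamus_to_cortex: 0.0
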