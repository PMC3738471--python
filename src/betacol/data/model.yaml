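# Bundled two-column laminar model definition.
#
# Units: conductances mS/cm^2, potentials mV, capacitance uF/cm^2,
# currents uA/cm^2, times ms, rates Hz.  A negative tonic mean depolarizes.
# Any value here can be overridden by a user config merged on top.

kinetics_table: kramer-reduced-v1

defaults:
  g_naf: 200.0
  g_kdr: 20.0
  g_leak: 2.5
  c_m: 0.9
  e_na: 50.0
  e_k: -100.0
  e_leak_exc: -67.0
  e_leak_inh: -65.0
  e_ca: 125.0
  # which parameter is halved for L2/3 RS cells (leak conductance by default)
  l23_rs_halved_param: g_leak

# electrical coupling between L5 pyramidal compartments (mS/cm^2)
coupling:
  axon_soma: 3.0
  soma_dendrite: 1.0

populations:
  l23_rs:
    family: exc
    excitatory: true
    compartments:
      soma: {g_m: 0.5, g_cah: 0.0, tonic_mean: 0.0, tonic_std: 0.5, g_epsc: 0.2}
  l23_fs:
    family: fs
    excitatory: false
    compartments:
      soma: {g_m: 0.0, g_cah: 0.0, tonic_mean: 0.0, tonic_std: 0.5, g_epsc: 0.02,
             g_naf: 35.0, g_kdr: 9.0, g_leak: 0.5, e_na: 55.0, e_k: -90.0, c_m: 0.5}
  l23_si:
    family: inh
    excitatory: false
    compartments:
      soma: {g_m: 8.0, g_cah: 0.0, tonic_mean: -1.0, tonic_std: 0.5, g_epsc: 0.0,
             g_naf: 100.0}
  l4_e:
    family: exc
    excitatory: true
    compartments:
      soma: {g_m: 0.3, g_cah: 0.0, tonic_mean: -1.0, tonic_std: 0.0, g_epsc: 1.0,
             g_leak: 4.5}
  l4_fs:
    family: fs
    excitatory: false
    compartments:
      soma: {g_m: 0.0, g_cah: 0.0, tonic_mean: 2.0, tonic_std: 0.5, g_epsc: 0.03,
             g_naf: 35.0, g_kdr: 9.0, g_leak: 0.5, e_na: 55.0, e_k: -90.0, c_m: 0.5}
  l5_ib:
    family: exc
    excitatory: true
    spike_compartment: axon
    compartments:
      axon: {g_m: 2.0, g_cah: 0.0, tonic_mean: 1.0, tonic_std: 0.1, g_epsc: 0.0}
      soma: {g_m: 0.0, g_cah: 0.0, tonic_mean: 1.0, tonic_std: 0.1, g_epsc: 0.0}
      dendrite: {g_m: 4.0, g_cah: 4.0, tonic_mean: 2.0, tonic_std: 0.3, g_epsc: 3.0,
                 g_leak: 1.5}
  l5_rs:
    family: exc
    excitatory: true
    spike_compartment: axon
    compartments:
      axon: {g_m: 2.0, g_cah: 0.0, tonic_mean: 1.0, tonic_std: 0.1, g_epsc: 0.0}
      soma: {g_m: 0.0, g_cah: 0.0, tonic_mean: 1.0, tonic_std: 0.1, g_epsc: 0.0}
      dendrite: {g_m: 4.0, g_cah: 1.6, tonic_mean: 2.0, tonic_std: 0.3, g_epsc: 3.0,
                 g_leak: 1.5}
  l5_fs:
    family: fs
    excitatory: false
    compartments:
      soma: {g_m: 0.0, g_cah: 0.0, tonic_mean: 0.0, tonic_std: 0.5, g_epsc: 0.0,
             g_naf: 35.0, g_kdr: 9.0, g_leak: 0.5, e_na: 55.0, e_k: -90.0, c_m: 0.5}
  l5_si:
    family: inh
    excitatory: false
    compartments:
      soma: {g_m: 4.0, g_cah: 0.0, tonic_mean: -1.0, tonic_std: 0.8, g_epsc: 0.0,
             g_naf: 100.0}

# receptor kinetics: rise/decay (ms) and reversal (mV)
receptors:
  ampa: {tau_rise: 0.25, tau_decay: 1.0, e_rev: 0.0}
  gaba_fs: {tau_rise: 0.5, tau_decay: 8.0, e_rev: -80.0}
  nmda: {tau_rise: 5.0, tau_decay: 100.0, e_rev: 0.0}
  gaba_si: {tau_rise: 0.5, tau_decay: 20.0, e_rev: -80.0}
  slow_exc_l5_to_l23si: {tau_rise: 2.5, tau_decay: 50.0, e_rev: 0.0}

# presynaptic gate drive: 1/(1+exp(-(v_pre - v_thresh)/v_slope))
synapse_drive: {v_thresh: 0.0, v_slope: 2.0}
nmda_mg_block: false

# connectivity map: for each presynaptic population, a list of
# [post_population, n_pre_per_post, g_max].  The receptor follows from the
# presynaptic class (AMPA for excitatory cells, FS- or SI-type GABA for
# interneurons) except the slow L5-pyramid -> L2/3 SI excitation.
connectivity:
  l23_rs:
    - [l23_rs, 5, 0.22]
    - [l23_fs, 10, 0.3]
    - [l23_si, 10, 0.03]
    - [l5_ib, 20, 0.212]
    - [l5_rs, 20, 0.212]
  l23_fs:
    - [l23_rs, 5, 0.4]
    - [l23_fs, 8, 0.6]
    - [l23_si, 5, 0.1]
    - [l4_e, 5, 0.4]
  l23_si:
    - [l23_rs, 5, 0.1]
    - [l23_fs, 5, 0.2]
  l4_e:
    - [l23_rs, 5, 0.2]
    - [l4_e, 10, 0.4]
    - [l4_fs, 10, 0.2]
    - [l5_ib, 10, 0.212]
    - [l5_rs, 10, 0.212]
    - [l5_fs, 20, 0.3]
  l4_fs:
    - [l23_rs, 5, 0.02]
    - [l4_e, 10, 1.0]
    - [l4_fs, 10, 0.3]
  l5_ib:
    - [l23_fs, 2, 0.2]
    - [l23_si, 2, 0.2]
    - [l5_ib, 10, 0.02]
    - [l5_rs, 10, 0.02]
    - [l5_fs, 10, 0.12]
    - [l5_si, 10, 0.12]
  l5_rs:
    - [l23_fs, 2, 0.2]
    - [l23_si, 2, 0.2]
    - [l5_ib, 10, 0.02]
    - [l5_rs, 10, 0.02]
    - [l5_fs, 10, 0.05]
    - [l5_si, 10, 0.15]
  l5_fs:
    - [l5_ib, 20, 0.1]
    - [l5_rs, 20, 0.1]
    - [l5_fs, 20, 0.5]
    - [l5_si, 10, 0.3]
  l5_si:
    - [l4_fs, 10, 0.4]
    - [l5_ib, 20, 0.3]
    - [l5_rs, 10, 0.3]
    - [l5_fs, 10, 0.6]
    - [l5_si, 20, 0.4]

# 25% of L2/3 FS and SI cells additionally receive NMDA contacts from
# 10 L2/3 RS cells
nmda_rule:
  fraction: 0.25
  n_pre: 10
  g_max: {l23_fs: 0.04, l23_si: 0.03}

# intercolumnar ascending excitation: L5 pyramids -> other-column L2/3
# interneurons; counts and kinetics mirror the intracolumnar projection,
# with the -> SI conductance boosted by 50%
intercolumnar:
  si_boost: 1.5
  rules:
    - [l5_ib, l23_fs, 2, 0.2]
    - [l5_ib, l23_si, 2, 0.2]
    - [l5_rs, l23_fs, 2, 0.2]
    - [l5_rs, l23_si, 2, 0.2]

n_per_population: 20

# external EPSC trains: 2 ms conductance decay; arrivals superpose
# ("sum", one exponential per arrival) or saturate ("reset")
external_inputs:
  epsc_decay_tau: 2.0
  epsc_mode: sum
  background: {rate: 50.0, targets: [l23_rs]}
  bottom_up: {rate: 100.0, targets: [l4_e, l4_fs]}
  top_down: {freq: 20.0, targets: [l5_ib, l5_rs], compartment: dendrite}
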