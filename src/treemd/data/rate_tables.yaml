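# Toy per-element rate tables for hydrogen and oxygen.
#
# These are order-of-magnitude stand-ins for ab-initio atomic data: binding
# energies are the usual neutral-atom values, photoionization cross sections
# are evaluated at the default 7.12 keV photon energy, core-hole decay rates
# are typical K-shell values for oxygen.  They are *inputs* to the simulator;
# nothing in the solver layer depends on their absolute accuracy.
#
# units: binding_ev [eV], sigma_ph_mb [Mbarn] (at the configured photon
# energy), rates [1/fs], auger_energy_ev [eV], mass_amu [amu].
elements:
  H:
    mass_amu: 1.008
    orbitals:
      - {name: 1s, capacity: 2, occupation: 1, binding_ev: 13.6, sigma_ph_mb: 1.0e-5}
    auger_rate_per_fs: 0.0
    fluor_rate_per_fs: 0.0
    auger_energy_ev: 0.0
  O:
    mass_amu: 15.999
    orbitals:
      - {name: 1s, capacity: 2, occupation: 2, binding_ev: 543.1, sigma_ph_mb: 0.10}
      - {name: 2s, capacity: 2, occupation: 2, binding_ev: 41.6, sigma_ph_mb: 2.0e-3}
      - {name: 2p, capacity: 6, occupation: 4, binding_ev: 13.6, sigma_ph_mb: 1.2e-3}
    # K-hole decay (KLL Auger dominates; fluorescence yield ~1%)
    auger_rate_per_fs: 0.25
    fluor_rate_per_fs: 0.003
    auger_energy_ev: 500.0
impact_ionization:
  # Lotz-type model sigma(E) = a * N * ln(E/B) / (E*B), a in Mbarn*eV^2
  lotz_a_mb_ev2: 4.5e4
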