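# Default low-LET spur model (version 1): the initial condition of the chemical
# stage at ~1 ps, emulating what a track-structure physical + physico-chemical
# simulation hands to the chemistry stage.
#
# Yields are classic spur-diffusion-model initial (1 ps) yields for low-LET
# electron radiolysis, expressed per 100 eV of deposited energy, organised by
# water-decomposition channel so that every generated spur is exactly charge
# neutral and exactly redox balanced:
#   ionization:   H2O -> e_aq + OH + H3O+    (4.78 / 100 eV)
#   h_atom:       H2O -> H + OH              (0.62 / 100 eV)
#   molecular_h2: 2 H2O -> H2 + 2 OH        (0.15 / 100 eV)
# Implied per-species yields: e_aq 4.78, OH 5.70, H 0.62, H2 0.15, H3O+ 4.78.
#
# sigma_nm: per-species rms Gaussian displacement (each Cartesian axis) about
# the spur centre; the hydrated electron thermalizes much farther than the
# heavy species.
energy_per_spur_eV: 62.5
creation_time_ns: 1.0e-3
sigma_nm:
  e_aq: 2.3
  default: 0.85
channels:
  ionization:
    yield_per_100eV: 4.78
    products: [e_aq, OH, H3O+]
  h_atom:
    yield_per_100eV: 0.62
    products: [H, OH]
  molecular_h2:
    yield_per_100eV: 0.15
    products: [H2, OH, OH]
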