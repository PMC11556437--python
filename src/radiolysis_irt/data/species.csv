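# Default species table (version 1).
# Columns:
#   name            species identifier
#   charge          elementary charges
#   is_background   1 for species that are always homogeneously distributed (H2O)
#   d25             diffusion coefficient at 25 C, units 1e-9 m^2/s
#   d_form, d_p1    temperature law for D(t) on [25, 150] C:
#                     arrhenius: D(t) = d25 * exp(Ea/Rgas * (1/298.15 - 1/T)),
#                                d_p1 = Ea in kJ/mol
# Room-temperature values are the GEANT4-DNA chemistry defaults; activation
# energies follow high-temperature water-radiolysis compilations (hydrated
# electron ~20 kJ/mol; neutral radicals/molecules near water self-diffusion;
# Grotthuss-assisted ions weaker).
name,charge,is_background,d25,d_form,d_p1
e_aq,-1,0,4.9,arrhenius,20.3
OH,0,0,2.8,arrhenius,17.0
H,0,0,7.0,arrhenius,17.0
H2,0,0,4.8,arrhenius,17.0
H2O2,0,0,2.3,arrhenius,17.0
H3O+,1,0,9.0,arrhenius,10.5
OH-,-1,0,5.0,arrhenius,12.6
HO2,0,0,2.0,arrhenius,17.0
H2O,0,1,2.3,arrhenius,18.0
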