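# Default chemical-stage reaction scheme (version 1): the canonical sub-microsecond
# set of spur reactions plus background-scavenging channels.  Room-temperature rate
# constants are the GEANT4-DNA chemistry defaults; temperature laws follow
# high-temperature water-radiolysis rate compilations.  The OH+OH self-reaction
# rate decreases mildly with temperature, per those compilations.
# Columns:
#   id              reaction identifier
#   reactants       '|'-separated species names (1 or 2)
#   products        '|'-separated species names (may be empty; water omitted)
#   type_tag        reaction-type classification 1-6 (6 = background scavenging)
#   kinetics_class  fully_diffusion_controlled | partially_diffusion_controlled |
#                   background_scavenging
#   background      for background_scavenging: which reactant is the background one
#   k_form, k25, k_p1   temperature law for k(t), M^-1 s^-1, on [25, 150] C:
#       arrhenius: k(t) = k25 * exp(Ea/Rgas * (1/298.15 - 1/T)), k_p1 = Ea kJ/mol
#       linlog:    log10 k(t) = log10 k25 + k_p1 * (t - 25), k_p1 in 1/degC
id,reactants,products,type_tag,kinetics_class,background,k_form,k25,k_p1
R1,e_aq|e_aq,H2|OH-|OH-,2,partially_diffusion_controlled,,arrhenius,5.5e9,20.3
R2,e_aq|OH,OH-,2,partially_diffusion_controlled,,arrhenius,2.95e10,8.0
R3,e_aq|H,H2|OH-,1,partially_diffusion_controlled,,arrhenius,2.65e10,14.0
R4,e_aq|H3O+,H,3,fully_diffusion_controlled,,arrhenius,2.11e10,12.0
R5,e_aq|H2O2,OH|OH-,1,partially_diffusion_controlled,,arrhenius,1.41e10,15.7
R6,OH|OH,H2O2,2,partially_diffusion_controlled,,linlog,4.4e9,-6.0e-4
R7,OH|H,,2,partially_diffusion_controlled,,arrhenius,1.44e10,9.0
R8,H|H,H2,2,partially_diffusion_controlled,,arrhenius,1.2e10,14.0
R9,H3O+|OH-,,3,fully_diffusion_controlled,,arrhenius,1.43e11,9.0
R10,e_aq|H3O+,H,6,background_scavenging,H3O+,arrhenius,2.11e10,12.0
R11,H|OH-,e_aq,6,background_scavenging,OH-,arrhenius,2.51e7,38.0
R12,e_aq|H2O,H|OH-,6,background_scavenging,H2O,arrhenius,1.58e1,31.0
R13,OH-|H3O+,,6,background_scavenging,H3O+,arrhenius,1.43e11,9.0
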