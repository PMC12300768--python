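# IPOL-0.13: rigid three-site Drude-polarizable water with a tetrahedral
# angle.  The source table prints only the partial charges; the Drude charge
# and polarizability must be supplied by the user before running
# polarization analyses (null values are rejected by those code paths).
name: IPOL-0.13
geometry:
  rigid: true
  r_oh: 1.0          # Angstrom (model-definition value; not printed with the charges)
  hoh_angle: 109.47  # degrees
site_charges:
  O: -0.669
  H1: 0.3345
  H2: 0.3345
drude:
  host: O
  q_d: null
  alpha: null
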