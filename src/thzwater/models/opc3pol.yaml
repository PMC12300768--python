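# OPC3-pol: rigid three-site Drude-polarizable water with a tetrahedral
# angle, built on the OPC3 geometry.  The permanent/induced partition of
# this model is not clean (the heavy Drude particle carries half the oxygen
# mass); here the printed site charges are treated as the permanent set and
# the Drude pair as purely induced.  Drude charge/polarizability are not
# printed with the charges and must be supplied by the user.
name: OPC3-pol
geometry:
  rigid: true
  r_oh: 0.97888      # Angstrom (OPC3 geometry)
  hoh_angle: 109.47  # degrees
site_charges:
  O: -0.610
  H1: 0.305
  H2: 0.305
drude:
  host: O
  q_d: null
  alpha: null
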