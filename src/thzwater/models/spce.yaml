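# SPC/E: rigid, non-polarizable three-site water.
# Charges from the standard SPC/E parameterization; bond length and the
# tetrahedral angle are the canonical model geometry.
name: SPC/E
geometry:
  rigid: true
  r_oh: 1.0          # Angstrom
  hoh_angle: 109.47  # degrees
site_charges:
  O: -0.848
  H1: 0.424
  H2: 0.424
# Elevated oxygen polarizability used when induced dipoles are added
# post-trajectory (the model itself carries no polarization).
post_polarization:
  site: O
  alpha: 1.14  # A^3
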