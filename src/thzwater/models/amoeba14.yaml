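# AMOEBA14: flexible multipole water.  Every atom carries a charge, a
# permanent dipole and a traceless quadrupole expressed in its atomic local
# frame (oxygen z = bisector toward the hydrogen midpoint; hydrogen z = unit
# vector from H toward O, x in-plane pointing toward the molecular
# interior).  Induced dipoles are self-consistent point dipoles on oxygen.
name: AMOEBA14
geometry:
  rigid: false
  r_oh: 0.9565       # Angstrom, equilibrium monomer bond length
  hoh_angle: 107.91  # degrees, equilibrium monomer angle
site_charges:
  O: -0.42616
  H1: 0.21308
  H2: 0.21308
polarizability:     # A^3, isotropic, oxygen only
  O: 1.47
atomic_dipoles:     # Debye, components [x, y, z] in the atomic local frame
  O:  [0.0, 0.0, 0.159]
  H1: [-0.257, 0.0, -0.691]
  H2: [-0.257, 0.0, -0.691]
atomic_quadrupoles: # D*A, symmetric traceless tensors in the local frame
  O:
    xx: 0.236
    yy: -0.312
    zz: 0.075
  H1:
    xx: 0.165
    yy: 0.120
    zz: -0.286
    xz: -0.094
  H2:
    xx: 0.165
    yy: 0.120
    zz: -0.286
    xz: -0.094
# Simulation engines expect one third of the tabulated quadrupole values.
quadrupole_scale_convention: one_third
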