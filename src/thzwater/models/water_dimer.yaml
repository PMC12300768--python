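# CHELPG partial charges of the hydrogen-bonded water dimer (donor molecule
# 1 donates H11 to acceptor oxygen O2).  The fragments are individually
# non-neutral (charge transfer ~0.043 e across the hydrogen bond); only the
# six-site dimer as a whole is neutral, so per-fragment dipoles are
# origin-dependent and are reported about the fragment oxygen.
name: water-dimer
geometry:
  rigid: false
site_charges:
  O1: -0.810
  H11: 0.384
  H12: 0.383
  O2: -0.752
  H21: 0.394
  H22: 0.401
fragments:
  mol1: [O1, H11, H12]
  mol2: [O2, H21, H22]
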