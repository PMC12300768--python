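# SWM4-NDP: rigid four-site Drude-polarizable water.  The massless OM site
# sits 0.24 A from the oxygen toward the hydrogen midpoint and carries the
# oxygen charge; the Drude pair is attached to the real oxygen.
name: SWM4-NDP
geometry:
  rigid: true
  r_oh: 0.9572       # Angstrom
  hoh_angle: 104.52  # degrees
site_charges:
  O: 0.0
  OM: -1.11466
  H1: 0.55733
  H2: 0.55733
virtual_sites:
  - label: OM
    rule: bisector
    displacement: 0.24  # Angstrom, from O toward the H midpoint
drude:
  host: O
  q_d: -1.71636   # e (negative Drude charge)
  alpha: 0.97825  # A^3 = q_d^2 / k_d with k_d = 1000 kcal/mol/A^2
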