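# Electronic-state sidecar for 3-hexanone (CCC(=O)CCC), heavy-atom indices
# follow the SMILES order: 1-3 = C1-C3, 4 = carbonyl O, 5-7 = C4-C6.
#
# Dipole moment, the carbonyl bond length and the C/O net charges are the
# published AM1 values for this molecule.  The set_value entries for the
# carbonyl carbon (atom 3) and oxygen (atom 4) are the raw (unscaled) SET
# values, back-derived from their published dipole-scaled values by dividing
# out A_mu; the remaining carbons carry their published SET values directly.
name: 3-hexanone
dipole_debye: 2.6790
polar_group:
  c_index: 3
  x_index: 4
  bond_length_angstrom: 1.2342
atoms:
  - {index: 1, element: C, set_value: 0.9892}
  - {index: 2, element: C, set_value: 0.9998}
  - {index: 3, element: C, net_charge_e: 0.224, set_value: 0.22678}
  - {index: 4, element: O, net_charge_e: -0.288, set_value: 1.13459}
  - {index: 5, element: C, set_value: 0.9998}
  - {index: 6, element: C, set_value: 0.8988}
  - {index: 7, element: C, set_value: 0.9998}
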