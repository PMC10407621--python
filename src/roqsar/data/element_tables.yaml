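# Atomic and bond parameter tables for descriptor computation.
# version 1: user-overridable; pass a custom file to ElementTables.from_yaml.
version: 1

# Sanderson electronegativities (raw scale); values are divided by the
# carbon entry at load time so that carbon-relative EN(C) == 1 exactly.
sanderson_electronegativity:
  H: 2.592
  B: 2.275
  C: 2.746
  N: 3.194
  O: 3.654
  F: 4.000
  P: 2.515
  S: 2.957
  Cl: 3.475
  Br: 3.219
  I: 2.778

# Bond dipole moments (debye) used as diagonal weights of the dipole-weighted
# edge-adjacency matrix.  Keys follow bond_key(): alphabetical element pair
# joined by the order symbol (- single, = double, '#' triple, ':' aromatic).
# Carbon-carbon bonds of any order carry zero dipole by symmetry; values for
# heteroatom bonds are compiled from published bond dipole moments.
bond_dipole:
  C-C: 0.0
  C=C: 0.0
  "C#C": 0.0
  "C:C": 0.0
  C-Cl: 1.47
  Br-C: 1.38
  C-I: 1.19
  C-F: 1.41
  C-O: 0.74
  C=O: 2.40
  C-N: 0.45
  C=N: 1.40
  "C#N": 3.60
  "C:N": 1.40
  C-S: 0.90
  C=S: 2.00
  N-O: 0.30
  N=O: 2.00
  O-O: 0.0
  N-N: 0.0
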