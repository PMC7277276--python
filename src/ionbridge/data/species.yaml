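# Species definitions, CHARMM36 naming convention for the atoms that the
# analyses touch (phosphate oxygens OP4x/OP5x/OP3x, diester prefix OP1,
# hydroxyl/amine donors).  Lipids are coarse pseudo-atom sets: headgroup
# phosphorus + oxygens + H-bond hydrogens, a glycerol/COM bead (C2) and a
# tail bead (C218).  Offsets are Angstroms relative to the molecule anchor,
# defined for an outer-leaflet (upper, tails pointing down) orientation;
# the builder mirrors z for the inner leaflet.
#
# Fields per species:
#   kind: lipid | sterol | ion | water
#   charge: net charge (e)
#   headgroup_ref: atom anchoring leaflet assignment
#   atoms: [name, mass, dx, dy, dz]
#   donors: [[donor_atom, bonded_hydrogen], ...]
#   acceptors: [atom, ...]
#   anionic: heavy atoms eligible for cation salt bridges (deprotonated
#            phosphate/carboxylate oxygens; protonated positions excluded)
#   reference_area: per-lipid area (A^2) used for leaflet balance checks
#   shell_radius: first-solvation-shell radius (A), ions only

POPC:
  kind: lipid
  charge: 0
  headgroup_ref: P
  reference_area: 64.7
  atoms:
    - [P,    30.97,  0.0,  0.0,  0.0]
    - [OP11, 15.999, 1.2,  0.8,  0.3]
    - [OP12, 15.999, -1.2, 0.8,  0.3]
    - [N,    14.007, 0.0, -2.0,  1.5]
    - [C2,   12.011, 0.0,  0.0, -3.0]
    - [C218, 12.011, 0.0,  0.0, -12.0]
  donors: []
  acceptors: [OP11, OP12]
  anionic: []

DOPE:
  kind: lipid
  charge: 0
  headgroup_ref: P
  reference_area: 63.0
  atoms:
    - [P,    30.97,  0.0,  0.0,  0.0]
    - [OP11, 15.999, 1.2,  0.8,  0.3]
    - [OP12, 15.999, -1.2, 0.8,  0.3]
    - [N,    14.007, 0.0, -2.0,  1.8]
    - [HN1,  1.008,  0.0, -2.6,  2.6]
    - [C2,   12.011, 0.0,  0.0, -3.0]
    - [C218, 12.011, 0.0,  0.0, -12.0]
  donors: [[N, HN1]]
  acceptors: [OP11, OP12]
  anionic: []

DOPS:
  kind: lipid
  charge: -1
  headgroup_ref: P
  reference_area: 65.3
  atoms:
    - [P,    30.97,  0.0,  0.0,  0.0]
    - [OP11, 15.999, 1.2,  0.8,  0.3]
    - [OP12, 15.999, -1.2, 0.8,  0.3]
    - [N,    14.007, 0.0, -2.0,  2.0]
    - [HN1,  1.008,  0.0, -2.6,  2.8]
    - [O13,  15.999, 1.5, -2.5,  1.0]
    - [O14,  15.999, 2.5, -1.8,  1.0]
    - [C2,   12.011, 0.0,  0.0, -3.0]
    - [C218, 12.011, 0.0,  0.0, -12.0]
  donors: [[N, HN1]]
  acceptors: [OP11, OP12, O13, O14]
  anionic: [OP11, OP12, O13, O14]

CHL1:
  kind: sterol
  charge: 0
  headgroup_ref: O3
  reference_area: 40.0
  atoms:
    - [O3,  15.999, 0.0,  0.0,  0.0]
    - [H3,  1.008,  0.0,  0.8,  0.6]
    - [C3,  12.011, 0.0,  0.0, -1.5]
    - [C17, 12.011, 0.0,  0.0, -10.0]
  donors: [[O3, H3]]
  acceptors: [O3]
  anionic: []

PI:
  kind: lipid
  charge: -1
  headgroup_ref: P
  reference_area: 68.0
  atoms:
    - [P,    30.97,  0.0,  0.0,  0.0]
    - [OP11, 15.999, 1.2,  0.8,  0.3]
    - [OP12, 15.999, -1.2, 0.8,  0.3]
    - [O2,   15.999, 0.0, -2.2,  2.2]
    - [HO2,  1.008,  0.0, -2.7,  2.9]
    - [C2,   12.011, 0.0,  0.0, -3.0]
    - [C218, 12.011, 0.0,  0.0, -12.0]
  donors: [[O2, HO2]]
  acceptors: [OP11, OP12, O2]
  anionic: [OP11, OP12]

# PI(4,5)P2: 4-phosphate fully deprotonated (OP42/OP43/OP44); 5-phosphate
# protonated at OP52 (carries H52), so OP52 is absent from the anionic set.
PI45P2:
  kind: lipid
  charge: -4
  headgroup_ref: P
  reference_area: 70.0
  atoms:
    - [P,    30.97,  0.0,  0.0,  0.0]
    - [OP11, 15.999, 1.0,  1.0,  0.2]
    - [OP12, 15.999, -1.0, 1.0,  0.2]
    - [P4,   30.97,  2.2, -1.0,  1.8]
    - [OP42, 15.999, 3.2, -1.6,  2.4]
    - [OP43, 15.999, 2.6,  0.2,  2.6]
    - [OP44, 15.999, 1.4, -1.8,  2.6]
    - [P5,   30.97, -2.2, -1.0,  1.8]
    - [OP52, 15.999, -3.2, -1.6, 2.4]
    - [H52,  1.008, -3.7, -2.0,  3.0]
    - [OP53, 15.999, -2.6, 0.2,  2.6]
    - [OP54, 15.999, -1.4, -1.8, 2.6]
    - [O2,   15.999, 0.0, -2.2,  2.2]
    - [HO2,  1.008,  0.0, -2.7,  2.9]
    - [C2,   12.011, 0.0,  0.0, -3.0]
    - [C218, 12.011, 0.0,  0.0, -12.0]
  donors: [[O2, HO2], [OP52, H52]]
  acceptors: [OP11, OP12, OP42, OP43, OP44, OP53, OP54, O2]
  anionic: [OP11, OP12, OP42, OP43, OP44, OP53, OP54]

PI35P2:
  kind: lipid
  charge: -4
  headgroup_ref: P
  reference_area: 70.0
  atoms:
    - [P,    30.97,  0.0,  0.0,  0.0]
    - [OP11, 15.999, 1.0,  1.0,  0.2]
    - [OP12, 15.999, -1.0, 1.0,  0.2]
    - [P3,   30.97,  2.2, -1.0,  1.8]
    - [OP32, 15.999, 3.2, -1.6,  2.4]
    - [OP33, 15.999, 2.6,  0.2,  2.6]
    - [OP34, 15.999, 1.4, -1.8,  2.6]
    - [P5,   30.97, -2.2, -1.0,  1.8]
    - [OP52, 15.999, -3.2, -1.6, 2.4]
    - [H52,  1.008, -3.7, -2.0,  3.0]
    - [OP53, 15.999, -2.6, 0.2,  2.6]
    - [OP54, 15.999, -1.4, -1.8, 2.6]
    - [O2,   15.999, 0.0, -2.2,  2.2]
    - [HO2,  1.008,  0.0, -2.7,  2.9]
    - [C2,   12.011, 0.0,  0.0, -3.0]
    - [C218, 12.011, 0.0,  0.0, -12.0]
  donors: [[O2, HO2], [OP52, H52]]
  acceptors: [OP11, OP12, OP32, OP33, OP34, OP53, OP54, O2]
  anionic: [OP11, OP12, OP32, OP33, OP34, OP53, OP54]

TIP3:
  kind: water
  charge: 0
  headgroup_ref: OH2
  atoms:
    - [OH2, 15.999, 0.0,  0.0, 0.0]
    - [H1,  1.008,  0.76, 0.59, 0.0]
    - [H2,  1.008, -0.76, 0.59, 0.0]
  donors: [[OH2, H1], [OH2, H2]]
  acceptors: [OH2]
  anionic: []

SOD: {kind: ion, charge: 1,  shell_radius: 3.0, atoms: [[SOD, 22.99,  0.0, 0.0, 0.0]]}
POT: {kind: ion, charge: 1,  shell_radius: 3.0, atoms: [[POT, 39.098, 0.0, 0.0, 0.0]]}
MGA: {kind: ion, charge: 2,  shell_radius: 2.3, atoms: [[MGA, 24.305, 0.0, 0.0, 0.0]]}
CAL: {kind: ion, charge: 2,  shell_radius: 2.6, atoms: [[CAL, 40.078, 0.0, 0.0, 0.0]]}
CLA: {kind: ion, charge: -1, atoms: [[CLA, 35.45, 0.0, 0.0, 0.0]]}
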