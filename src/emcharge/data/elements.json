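{
 "covalent_radius": {
  "Ag": 1.45,
  "Al": 1.21,
  "Ar": 1.06,
  "As": 1.19,
  "Au": 1.36,
  "B": 0.84,
  "Ba": 2.15,
  "Be": 0.96,
  "Bi": 1.48,
  "Br": 1.2,
  "C": 0.76,
  "Ca": 1.76,
  "Cd": 1.44,
  "Cl": 1.02,
  "Co": 1.5,
  "Cr": 1.39,
  "Cs": 2.44,
  "Cu": 1.32,
  "F": 0.57,
  "Fe": 1.52,
  "Ga": 1.22,
  "Ge": 1.2,
  "H": 0.31,
  "He": 0.28,
  "Hg": 1.32,
  "I": 1.39,
  "In": 1.42,
  "K": 2.03,
  "Kr": 1.16,
  "Li": 1.28,
  "Mg": 1.41,
  "Mn": 1.61,
  "Mo": 1.54,
  "N": 0.71,
  "Na": 1.66,
  "Ne": 0.58,
  "Ni": 1.24,
  "O": 0.66,
  "P": 1.07,
  "Pb": 1.46,
  "Pd": 1.39,
  "Pt": 1.36,
  "Rb": 2.2,
  "Rh": 1.42,
  "Ru": 1.46,
  "S": 1.05,
  "Sb": 1.39,
  "Sc": 1.7,
  "Se": 1.2,
  "Si": 1.11,
  "Sn": 1.39,
  "Sr": 1.95,
  "Te": 1.38,
  "Ti": 1.6,
  "V": 1.53,
  "W": 1.62,
  "Xe": 1.4,
  "Zn": 1.22
 },
 "pauling_en": {
  "Ag": 1.93,
  "Al": 1.61,
  "As": 2.18,
  "Au": 2.54,
  "B": 2.04,
  "Ba": 0.89,
  "Be": 1.57,
  "Br": 2.96,
  "C": 2.55,
  "Ca": 1.0,
  "Cd": 1.69,
  "Cl": 3.16,
  "Co": 1.88,
  "Cr": 1.66,
  "Cs": 0.79,
  "Cu": 1.9,
  "F": 3.98,
  "Fe": 1.83,
  "Ga": 1.81,
  "Ge": 2.01,
  "H": 2.2,
  "Hg": 2.0,
  "I": 2.66,
  "K": 0.82,
  "Li": 0.98,
  "Mg": 1.31,
  "Mn": 1.55,
  "N": 3.04,
  "Na": 0.93,
  "Ni": 1.91,
  "O": 3.44,
  "P": 2.19,
  "Pb": 2.33,
  "Pt": 2.28,
  "Rb": 0.82,
  "S": 2.58,
  "Sb": 2.05,
  "Se": 2.55,
  "Si": 1.9,
  "Sn": 1.96,
  "Sr": 0.95,
  "Te": 2.1,
  "Ti": 1.54,
  "Zn": 1.65
 },
 "valence_electrons": {
  "Ag": 11,
  "Al": 3,
  "Ar": 8,
  "As": 5,
  "Au": 11,
  "B": 3,
  "Ba": 2,
  "Be": 2,
  "Br": 7,
  "C": 4,
  "Ca": 2,
  "Cd": 12,
  "Cl": 7,
  "Co": 9,
  "Cr": 6,
  "Cs": 1,
  "Cu": 11,
  "F": 7,
  "Fe": 8,
  "Ga": 3,
  "Ge": 4,
  "H": 1,
  "He": 2,
  "Hg": 12,
  "I": 7,
  "In": 3,
  "K": 1,
  "Kr": 8,
  "Li": 1,
  "Mg": 2,
  "Mn": 7,
  "N": 5,
  "Na": 1,
  "Ne": 8,
  "Ni": 10,
  "O": 6,
  "P": 5,
  "Pb": 4,
  "Pt": 10,
  "Rb": 1,
  "S": 6,
  "Sb": 5,
  "Se": 6,
  "Si": 4,
  "Sn": 4,
  "Sr": 2,
  "Te": 6,
  "Ti": 4,
  "Xe": 8,
  "Zn": 12
 }
}
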