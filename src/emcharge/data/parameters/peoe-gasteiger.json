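{
 "format_version": "1",
 "id": "peoe-gasteiger",
 "method": "peoe",
 "citation": "Gasteiger J., Marsili M. (1980) Iterative partial equalization of orbital electronegativity - a rapid access to atomic charges. Tetrahedron 36:3219-3228",
 "description": "Orbital electronegativity polynomial coefficients chi(q) = a + b q + c q^2",
 "scheme": "hyb",
 "units": {
  "a": "eV",
  "b": "eV/e",
  "c": "eV/e^2"
 },
 "common": {},
 "atom": [
  {
   "element": "H",
   "value": "*",
   "params": {
    "a": 7.17,
    "b": 6.24,
    "c": -0.56
   }
  },
  {
   "element": "C",
   "value": "sp3",
   "params": {
    "a": 7.98,
    "b": 9.18,
    "c": 1.88
   }
  },
  {
   "element": "C",
   "value": "sp2",
   "params": {
    "a": 8.79,
    "b": 9.32,
    "c": 1.51
   }
  },
  {
   "element": "C",
   "value": "sp",
   "params": {
    "a": 10.39,
    "b": 9.45,
    "c": 0.73
   }
  },
  {
   "element": "N",
   "value": "sp3",
   "params": {
    "a": 11.54,
    "b": 10.82,
    "c": 1.36
   }
  },
  {
   "element": "N",
   "value": "sp2",
   "params": {
    "a": 12.87,
    "b": 11.15,
    "c": 0.85
   }
  },
  {
   "element": "N",
   "value": "sp",
   "params": {
    "a": 15.68,
    "b": 11.7,
    "c": -0.27
   }
  },
  {
   "element": "O",
   "value": "sp3",
   "params": {
    "a": 14.18,
    "b": 12.92,
    "c": 1.39
   }
  },
  {
   "element": "O",
   "value": "sp2",
   "params": {
    "a": 17.07,
    "b": 13.79,
    "c": 0.47
   }
  },
  {
   "element": "F",
   "value": "*",
   "params": {
    "a": 14.66,
    "b": 13.85,
    "c": 2.31
   }
  },
  {
   "element": "Cl",
   "value": "*",
   "params": {
    "a": 11.0,
    "b": 9.69,
    "c": 1.35
   }
  },
  {
   "element": "Br",
   "value": "*",
   "params": {
    "a": 10.08,
    "b": 8.47,
    "c": 1.16
   }
  },
  {
   "element": "I",
   "value": "*",
   "params": {
    "a": 9.9,
    "b": 7.96,
    "c": 0.96
   }
  },
  {
   "element": "S",
   "value": "*",
   "params": {
    "a": 10.14,
    "b": 9.13,
    "c": 1.38
   }
  }
 ]
}
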