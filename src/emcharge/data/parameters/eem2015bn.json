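{
 "format_version": "1",
 "id": "eem2015bn",
 "method": "eem",
 "citation": "Geidl S. et al. (2015) High-quality and universal empirical atomic charges for chemoinformatics applications. J Cheminformatics 7:59",
 "description": "EEM parameters fitted to B3LYP/6-311G, NPA reference charges",
 "scheme": "hbo",
 "units": {
  "A": "model units (electronegativity-like)",
  "B": "model units (hardness-like)",
  "kappa": "model units"
 },
 "common": {
  "kappa": 0.2509
 },
 "atom": [
  {
   "element": "Br",
   "value": "1",
   "params": {
    "A": 2.4244,
    "B": 0.7511
   }
  },
  {
   "element": "C",
   "value": "1",
   "params": {
    "A": 2.4992,
    "B": 0.322
   }
  },
  {
   "element": "C",
   "value": "2",
   "params": {
    "A": 2.5065,
    "B": 0.3173
   }
  },
  {
   "element": "C",
   "value": "3",
   "params": {
    "A": 2.4617,
    "B": 0.3489
   }
  },
  {
   "element": "Cl",
   "value": "1",
   "params": {
    "A": 2.5104,
    "B": 0.8364
   }
  },
  {
   "element": "F",
   "value": "1",
   "params": {
    "A": 3.0028,
    "B": 1.2433
   }
  },
  {
   "element": "H",
   "value": "1",
   "params": {
    "A": 2.3864,
    "B": 0.6581
   }
  },
  {
   "element": "I",
   "value": "1",
   "params": {
    "A": 2.3272,
    "B": 0.9303
   }
  },
  {
   "element": "N",
   "value": "1",
   "params": {
    "A": 2.5891,
    "B": 0.4072
   }
  },
  {
   "element": "N",
   "value": "2",
   "params": {
    "A": 2.5568,
    "B": 0.2949
   }
  },
  {
   "element": "N",
   "value": "3",
   "params": {
    "A": 2.5348,
    "B": 0.4025
   }
  },
  {
   "element": "O",
   "value": "1",
   "params": {
    "A": 2.6342,
    "B": 0.4041
   }
  },
  {
   "element": "O",
   "value": "2",
   "params": {
    "A": 2.6588,
    "B": 0.4232
   }
  },
  {
   "element": "P",
   "value": "1",
   "params": {
    "A": 2.3898,
    "B": 0.1902
   }
  },
  {
   "element": "P",
   "value": "2",
   "params": {
    "A": 2.2098,
    "B": 0.3281
   }
  },
  {
   "element": "S",
   "value": "1",
   "params": {
    "A": 2.4506,
    "B": 0.2404
   }
  },
  {
   "element": "S",
   "value": "2",
   "params": {
    "A": 2.4884,
    "B": 0.2043
   }
  }
 ]
}
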