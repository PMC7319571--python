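{
 "format_version": "1",
 "id": "eem2015hn",
 "method": "eem",
 "citation": "Geidl S. et al. (2015) High-quality and universal empirical atomic charges for chemoinformatics applications. J Cheminformatics 7:59",
 "description": "EEM parameters fitted to HF/6-31G*, NPA reference charges",
 "scheme": "hbo",
 "units": {
  "A": "model units (electronegativity-like)",
  "B": "model units (hardness-like)",
  "kappa": "model units"
 },
 "common": {
  "kappa": 0.2399
 },
 "atom": [
  {
   "element": "Br",
   "value": "1",
   "params": {
    "A": 2.44,
    "B": 0.6527
   }
  },
  {
   "element": "C",
   "value": "1",
   "params": {
    "A": 2.4887,
    "B": 0.3054
   }
  },
  {
   "element": "C",
   "value": "2",
   "params": {
    "A": 2.4975,
    "B": 0.2961
   }
  },
  {
   "element": "C",
   "value": "3",
   "params": {
    "A": 2.4613,
    "B": 0.3176
   }
  },
  {
   "element": "Cl",
   "value": "1",
   "params": {
    "A": 2.5225,
    "B": 0.7933
   }
  },
  {
   "element": "F",
   "value": "1",
   "params": {
    "A": 3.0211,
    "B": 1.1977
   }
  },
  {
   "element": "H",
   "value": "1",
   "params": {
    "A": 2.3915,
    "B": 0.6277
   }
  },
  {
   "element": "I",
   "value": "1",
   "params": {
    "A": 2.3274,
    "B": 0.9211
   }
  },
  {
   "element": "N",
   "value": "1",
   "params": {
    "A": 2.5943,
    "B": 0.392
   }
  },
  {
   "element": "N",
   "value": "2",
   "params": {
    "A": 2.55,
    "B": 0.2781
   }
  },
  {
   "element": "N",
   "value": "3",
   "params": {
    "A": 2.5334,
    "B": 0.3718
   }
  },
  {
   "element": "O",
   "value": "1",
   "params": {
    "A": 2.6399,
    "B": 0.3945
   }
  },
  {
   "element": "O",
   "value": "2",
   "params": {
    "A": 2.6505,
    "B": 0.3819
   }
  },
  {
   "element": "P",
   "value": "1",
   "params": {
    "A": 2.3929,
    "B": 0.1732
   }
  },
  {
   "element": "P",
   "value": "2",
   "params": {
    "A": 2.1741,
    "B": 0.3192
   }
  },
  {
   "element": "S",
   "value": "1",
   "params": {
    "A": 2.4471,
    "B": 0.2396
   }
  },
  {
   "element": "S",
   "value": "2",
   "params": {
    "A": 2.4906,
    "B": 0.195
   }
  }
 ]
}
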