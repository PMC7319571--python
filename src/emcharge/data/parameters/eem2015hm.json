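{
 "format_version": "1",
 "id": "eem2015hm",
 "method": "eem",
 "citation": "Geidl S. et al. (2015) High-quality and universal empirical atomic charges for chemoinformatics applications. J Cheminformatics 7:59",
 "description": "EEM parameters fitted to HF/6-31G*, Mulliken reference charges",
 "scheme": "hbo",
 "units": {
  "A": "model units (electronegativity-like)",
  "B": "model units (hardness-like)",
  "kappa": "model units"
 },
 "common": {
  "kappa": 0.2002
 },
 "atom": [
  {
   "element": "Br",
   "value": "1",
   "params": {
    "A": 2.3428,
    "B": 0.7816
   }
  },
  {
   "element": "C",
   "value": "1",
   "params": {
    "A": 2.5014,
    "B": 0.2723
   }
  },
  {
   "element": "C",
   "value": "2",
   "params": {
    "A": 2.4885,
    "B": 0.2466
   }
  },
  {
   "element": "C",
   "value": "3",
   "params": {
    "A": 2.5154,
    "B": 0.2382
   }
  },
  {
   "element": "Cl",
   "value": "1",
   "params": {
    "A": 2.5259,
    "B": 0.8731
   }
  },
  {
   "element": "F",
   "value": "1",
   "params": {
    "A": 3.0186,
    "B": 1.1132
   }
  },
  {
   "element": "H",
   "value": "1",
   "params": {
    "A": 2.3751,
    "B": 0.6621
   }
  },
  {
   "element": "I",
   "value": "1",
   "params": {
    "A": 2.2884,
    "B": 0.6413
   }
  },
  {
   "element": "N",
   "value": "1",
   "params": {
    "A": 2.61,
    "B": 0.306
   }
  },
  {
   "element": "N",
   "value": "2",
   "params": {
    "A": 2.5657,
    "B": 0.2911
   }
  },
  {
   "element": "N",
   "value": "3",
   "params": {
    "A": 2.6077,
    "B": 0.7579
   }
  },
  {
   "element": "O",
   "value": "1",
   "params": {
    "A": 2.637,
    "B": 0.3444
   }
  },
  {
   "element": "O",
   "value": "2",
   "params": {
    "A": 2.6481,
    "B": 0.3992
   }
  },
  {
   "element": "P",
   "value": "1",
   "params": {
    "A": 2.4071,
    "B": 0.1508
   }
  },
  {
   "element": "P",
   "value": "2",
   "params": {
    "A": 2.1654,
    "B": 0.3259
   }
  },
  {
   "element": "S",
   "value": "1",
   "params": {
    "A": 2.4202,
    "B": 0.2502
   }
  },
  {
   "element": "S",
   "value": "2",
   "params": {
    "A": 2.4642,
    "B": 0.1834
   }
  }
 ]
}
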