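{
 "format_version": "1",
 "id": "eem2015ba",
 "method": "eem",
 "citation": "Geidl S. et al. (2015) High-quality and universal empirical atomic charges for chemoinformatics applications. J Cheminformatics 7:59",
 "description": "EEM parameters fitted to B3LYP/6-311G, AIM reference charges",
 "scheme": "hbo",
 "units": {
  "A": "model units (electronegativity-like)",
  "B": "model units (hardness-like)",
  "kappa": "model units"
 },
 "common": {
  "kappa": 0.2347
 },
 "atom": [
  {
   "element": "Br",
   "value": "1",
   "params": {
    "A": 2.4677,
    "B": 0.6479
   }
  },
  {
   "element": "C",
   "value": "1",
   "params": {
    "A": 2.4324,
    "B": 0.3192
   }
  },
  {
   "element": "C",
   "value": "2",
   "params": {
    "A": 2.4466,
    "B": 0.3033
   }
  },
  {
   "element": "C",
   "value": "3",
   "params": {
    "A": 2.2903,
    "B": 0.5332
   }
  },
  {
   "element": "Cl",
   "value": "1",
   "params": {
    "A": 2.6026,
    "B": 0.829
   }
  },
  {
   "element": "F",
   "value": "1",
   "params": {
    "A": 3.5158,
    "B": 1.9387
   }
  },
  {
   "element": "H",
   "value": "1",
   "params": {
    "A": 2.4238,
    "B": 0.5586
   }
  },
  {
   "element": "I",
   "value": "1",
   "params": {
    "A": 2.3614,
    "B": 0.8545
   }
  },
  {
   "element": "N",
   "value": "1",
   "params": {
    "A": 2.5997,
    "B": 0.3608
   }
  },
  {
   "element": "N",
   "value": "2",
   "params": {
    "A": 2.5691,
    "B": 0.2893
   }
  },
  {
   "element": "N",
   "value": "3",
   "params": {
    "A": 2.8223,
    "B": 0.5704
   }
  },
  {
   "element": "O",
   "value": "1",
   "params": {
    "A": 2.6633,
    "B": 0.389
   }
  },
  {
   "element": "O",
   "value": "2",
   "params": {
    "A": 2.6729,
    "B": 0.377
   }
  },
  {
   "element": "P",
   "value": "1",
   "params": {
    "A": 1.8934,
    "B": 0.4338
   }
  },
  {
   "element": "P",
   "value": "2",
   "params": {
    "A": 1.951,
    "B": 0.3597
   }
  },
  {
   "element": "S",
   "value": "1",
   "params": {
    "A": 2.4047,
    "B": 0.2955
   }
  },
  {
   "element": "S",
   "value": "2",
   "params": {
    "A": 2.4354,
    "B": 0.2083
   }
  }
 ]
}
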