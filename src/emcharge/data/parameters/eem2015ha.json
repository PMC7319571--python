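{
 "format_version": "1",
 "id": "eem2015ha",
 "method": "eem",
 "citation": "Geidl S. et al. (2015) High-quality and universal empirical atomic charges for chemoinformatics applications. J Cheminformatics 7:59",
 "description": "EEM parameters fitted to HF/6-31G*, AIM reference charges",
 "scheme": "hbo",
 "units": {
  "A": "model units (electronegativity-like)",
  "B": "model units (hardness-like)",
  "kappa": "model units"
 },
 "common": {
  "kappa": 0.1976
 },
 "atom": [
  {
   "element": "Br",
   "value": "1",
   "params": {
    "A": 2.4703,
    "B": 0.5387
   }
  },
  {
   "element": "C",
   "value": "1",
   "params": {
    "A": 2.4246,
    "B": 0.2757
   }
  },
  {
   "element": "C",
   "value": "2",
   "params": {
    "A": 2.4435,
    "B": 0.254
   }
  },
  {
   "element": "C",
   "value": "3",
   "params": {
    "A": 2.3121,
    "B": 0.4293
   }
  },
  {
   "element": "Cl",
   "value": "1",
   "params": {
    "A": 2.6037,
    "B": 0.6822
   }
  },
  {
   "element": "F",
   "value": "1",
   "params": {
    "A": 3.5439,
    "B": 1.7138
   }
  },
  {
   "element": "H",
   "value": "1",
   "params": {
    "A": 2.4264,
    "B": 0.5054
   }
  },
  {
   "element": "I",
   "value": "1",
   "params": {
    "A": 2.3592,
    "B": 0.7476
   }
  },
  {
   "element": "N",
   "value": "1",
   "params": {
    "A": 2.5998,
    "B": 0.2979
   }
  },
  {
   "element": "N",
   "value": "2",
   "params": {
    "A": 2.5682,
    "B": 0.2454
   }
  },
  {
   "element": "N",
   "value": "3",
   "params": {
    "A": 3.1655,
    "B": 0.8188
   }
  },
  {
   "element": "O",
   "value": "1",
   "params": {
    "A": 2.6575,
    "B": 0.3274
   }
  },
  {
   "element": "O",
   "value": "2",
   "params": {
    "A": 2.6633,
    "B": 0.3163
   }
  },
  {
   "element": "P",
   "value": "1",
   "params": {
    "A": 1.9271,
    "B": 0.3795
   }
  },
  {
   "element": "P",
   "value": "2",
   "params": {
    "A": 1.8428,
    "B": 0.3442
   }
  },
  {
   "element": "S",
   "value": "1",
   "params": {
    "A": 2.3953,
    "B": 0.2731
   }
  },
  {
   "element": "S",
   "value": "2",
   "params": {
    "A": 2.4313,
    "B": 0.1792
   }
  }
 ]
}
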