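{
 "format_version": "1",
 "id": "eem2015bm",
 "method": "eem",
 "citation": "Geidl S. et al. (2015) High-quality and universal empirical atomic charges for chemoinformatics applications. J Cheminformatics 7:59",
 "description": "EEM parameters fitted to B3LYP/6-311G, Mulliken reference charges",
 "scheme": "hbo",
 "units": {
  "A": "model units (electronegativity-like)",
  "B": "model units (hardness-like)",
  "kappa": "model units"
 },
 "common": {
  "kappa": 0.2212
 },
 "atom": [
  {
   "element": "Br",
   "value": "1",
   "params": {
    "A": 2.3439,
    "B": 0.7687
   }
  },
  {
   "element": "C",
   "value": "1",
   "params": {
    "A": 2.5204,
    "B": 0.3115
   }
  },
  {
   "element": "C",
   "value": "2",
   "params": {
    "A": 2.496,
    "B": 0.282
   }
  },
  {
   "element": "C",
   "value": "3",
   "params": {
    "A": 2.5081,
    "B": 0.2101
   }
  },
  {
   "element": "Cl",
   "value": "1",
   "params": {
    "A": 2.4991,
    "B": 1.0091
   }
  },
  {
   "element": "F",
   "value": "1",
   "params": {
    "A": 3.1106,
    "B": 1.6791
   }
  },
  {
   "element": "H",
   "value": "1",
   "params": {
    "A": 2.377,
    "B": 0.7138
   }
  },
  {
   "element": "I",
   "value": "1",
   "params": {
    "A": 2.2743,
    "B": 0.7498
   }
  },
  {
   "element": "N",
   "value": "1",
   "params": {
    "A": 2.6108,
    "B": 0.3459
   }
  },
  {
   "element": "N",
   "value": "2",
   "params": {
    "A": 2.5832,
    "B": 0.3836
   }
  },
  {
   "element": "N",
   "value": "3",
   "params": {
    "A": 2.5544,
    "B": 0.9373
   }
  },
  {
   "element": "O",
   "value": "1",
   "params": {
    "A": 2.6371,
    "B": 0.4076
   }
  },
  {
   "element": "O",
   "value": "2",
   "params": {
    "A": 2.6361,
    "B": 0.4612
   }
  },
  {
   "element": "P",
   "value": "1",
   "params": {
    "A": 2.4248,
    "B": 0.1646
   }
  },
  {
   "element": "P",
   "value": "2",
   "params": {
    "A": 2.1446,
    "B": 0.4045
   }
  },
  {
   "element": "S",
   "value": "1",
   "params": {
    "A": 2.4121,
    "B": 0.3125
   }
  },
  {
   "element": "S",
   "value": "2",
   "params": {
    "A": 2.4626,
    "B": 0.207
   }
  }
 ]
}
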