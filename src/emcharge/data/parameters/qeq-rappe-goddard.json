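{
 "format_version": "1",
 "id": "qeq-rappe-goddard",
 "method": "qeq",
 "citation": "Rappe A.K., Goddard W.A. III (1991) Charge equilibration for molecular dynamics simulations. J Phys Chem 95:3358-3363",
 "description": "Element electronegativities and idempotentials from the original QEq publication",
 "scheme": "plain",
 "units": {
  "chi": "eV",
  "J": "eV/e"
 },
 "common": {},
 "atom": [
  {
   "element": "Al",
   "value": "*",
   "params": {
    "chi": 4.06,
    "J": 7.18
   }
  },
  {
   "element": "B",
   "value": "*",
   "params": {
    "chi": 5.11,
    "J": 9.5
   }
  },
  {
   "element": "Br",
   "value": "*",
   "params": {
    "chi": 7.79,
    "J": 8.85
   }
  },
  {
   "element": "C",
   "value": "*",
   "params": {
    "chi": 5.343,
    "J": 10.126
   }
  },
  {
   "element": "Cl",
   "value": "*",
   "params": {
    "chi": 8.564,
    "J": 9.892
   }
  },
  {
   "element": "F",
   "value": "*",
   "params": {
    "chi": 10.874,
    "J": 14.948
   }
  },
  {
   "element": "H",
   "value": "*",
   "params": {
    "chi": 4.528,
    "J": 13.8904
   }
  },
  {
   "element": "I",
   "value": "*",
   "params": {
    "chi": 6.822,
    "J": 7.524
   }
  },
  {
   "element": "K",
   "value": "*",
   "params": {
    "chi": 2.421,
    "J": 3.84
   }
  },
  {
   "element": "Li",
   "value": "*",
   "params": {
    "chi": 3.006,
    "J": 4.772
   }
  },
  {
   "element": "N",
   "value": "*",
   "params": {
    "chi": 6.899,
    "J": 11.76
   }
  },
  {
   "element": "Na",
   "value": "*",
   "params": {
    "chi": 2.843,
    "J": 4.592
   }
  },
  {
   "element": "O",
   "value": "*",
   "params": {
    "chi": 8.741,
    "J": 13.364
   }
  },
  {
   "element": "P",
   "value": "*",
   "params": {
    "chi": 5.463,
    "J": 8.0
   }
  },
  {
   "element": "S",
   "value": "*",
   "params": {
    "chi": 6.928,
    "J": 8.972
   }
  },
  {
   "element": "Si",
   "value": "*",
   "params": {
    "chi": 4.168,
    "J": 6.974
   }
  }
 ]
}
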