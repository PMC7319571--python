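{
 "format_version": "1",
 "id": "eqeqc-ionization",
 "method": "eqeqc",
 "citation": "Martin-Noble G.C. et al. (2015) EQeq+C: An empirical bond-order-corrected extended charge equilibration method. J Chem Theory Comput 11:3364-3374",
 "description": "EQeq ionization-derived element values with bond-order corrections (correction table empty: corrections default to 0)",
 "scheme": "plain",
 "units": {
  "chi": "eV",
  "J": "eV/e",
  "D": "e"
 },
 "common": {},
 "atom": [
  {
   "element": "B",
   "value": "*",
   "params": {
    "chi": 4.28886,
    "J": 8.01828
   }
  },
  {
   "element": "Br",
   "value": "*",
   "params": {
    "chi": 7.5888,
    "J": 8.45041
   }
  },
  {
   "element": "C",
   "value": "*",
   "params": {
    "chi": 6.26106,
    "J": 9.99788
   }
  },
  {
   "element": "Cl",
   "value": "*",
   "params": {
    "chi": 8.28986,
    "J": 9.35428
   }
  },
  {
   "element": "F",
   "value": "*",
   "params": {
    "chi": 10.4116,
    "J": 14.02081
   }
  },
  {
   "element": "H",
   "value": "*",
   "params": {
    "chi": 7.1761,
    "J": 12.8438
   }
  },
  {
   "element": "I",
   "value": "*",
   "params": {
    "chi": 6.75502,
    "J": 7.39196
   }
  },
  {
   "element": "N",
   "value": "*",
   "params": {
    "chi": 7.232,
    "J": 14.604
   }
  },
  {
   "element": "O",
   "value": "*",
   "params": {
    "chi": 7.53956,
    "J": 12.15689
   }
  },
  {
   "element": "P",
   "value": "*",
   "params": {
    "chi": 5.60225,
    "J": 9.7115
   }
  },
  {
   "element": "S",
   "value": "*",
   "params": {
    "chi": 6.21855,
    "J": 8.2829
   }
  },
  {
   "element": "Si",
   "value": "*",
   "params": {
    "chi": 4.77026,
    "J": 6.76148
   }
  }
 ],
 "bond": []
}
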