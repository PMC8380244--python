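{
  "human_male": {
    "species": "human",
    "label": "male",
    "BW": 73.0,
    "BH": 1.76,
    "BSA": 1.90,
    "Hct": 0.43,
    "V_blo": 5.30,
    "V_tis": {"liv": 1.80, "spl": 0.150, "mus": 29.0, "bon": 8.07, "bra": 1.45, "kid": 0.310, "rob": 25.8},
    "D_tis": {"liv": 1.0, "spl": 1.0, "mus": 1.0, "bon": 1.3, "bra": 1.0, "kid": 1.0, "rob": 0.95},
    "Q_tis": {"liv": 99.5, "spl": 11.7, "mus": 66.3, "bon": 19.5, "bra": 46.8, "kid": 74.1, "rob": 72.2},
    "GFR": 6.92
  },
  "human_female": {
    "species": "human",
    "label": "female",
    "BW": 60.0,
    "BH": 1.63,
    "BSA": 1.66,
    "Hct": 0.38,
    "V_blo": 3.90,
    "V_tis": {"liv": 1.40, "spl": 0.130, "mus": 17.5, "bon": 6.00, "bra": 1.30, "kid": 0.275, "rob": 29.4},
    "D_tis": {"liv": 1.0, "spl": 1.0, "mus": 1.0, "bon": 1.3, "bra": 1.0, "kid": 1.0, "rob": 0.94},
    "Q_tis": {"liv": 95.6, "spl": 10.62, "mus": 42.5, "bon": 17.7, "bra": 42.5, "kid": 60.2, "rob": 85.0},
    "GFR": 6.045
  },
  "rat_young": {
    "species": "rat",
    "label": "young",
    "BW": 0.25,
    "BH": null,
    "BSA": null,
    "Hct": 0.43,
    "V_blo": 0.0160,
    "V_tis": {"liv": 0.00920, "spl": 0.000500, "mus": 0.101, "bon": 0.0140, "bra": 0.00140, "kid": 0.00180, "rob": 0.104},
    "D_tis": {"liv": 1.0, "spl": 1.0, "mus": 1.0, "bon": 1.3, "bra": 1.0, "kid": 1.0, "rob": 0.98},
    "Q_tis": {"liv": 0.867, "spl": 0.0997, "mus": 1.39, "bon": 0.608, "bra": 0.0997, "kid": 0.703, "rob": 1.22},
    "GFR": 0.0786
  },
  "rat_old": {
    "species": "rat",
    "label": "old",
    "BW": 0.48,
    "BH": null,
    "BSA": null,
    "Hct": 0.43,
    "V_blo": 0.0304,
    "V_tis": {"liv": 0.0174, "spl": 0.000950, "mus": 0.192, "bon": 0.0267, "bra": 0.00270, "kid": 0.00350, "rob": 0.200},
    "D_tis": {"liv": 1.0, "spl": 1.0, "mus": 1.0, "bon": 1.3, "bra": 1.0, "kid": 1.0, "rob": 0.97},
    "Q_tis": {"liv": 1.404, "spl": 0.161, "mus": 2.24, "bon": 0.984, "bra": 0.161, "kid": 1.14, "rob": 1.98},
    "GFR": 0.127
  }
}
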