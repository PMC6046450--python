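{
  "contaminant_otus": [
    "CONTAM_001",
    "CONTAM_002",
    "CONTAM_003",
    "CONTAM_004",
    "CONTAM_005",
    "CONTAM_006",
    "CONTAM_007",
    "CONTAM_008",
    "CONTAM_009",
    "CONTAM_010",
    "CONTAM_011",
    "CONTAM_012"
  ],
  "retention": {
    "BN01_1": 0.758886,
    "BN01_2": 0.844382,
    "BN01_3": 0.52672,
    "BN01_4": 0.477905,
    "BN01_5": 0.314475,
    "BN01_6": 0.558446,
    "BN02_1": 0.526834,
    "BN02_2": 0.919589,
    "BN02_3": 0.696986,
    "BN02_4": 0.340093,
    "BN02_5": 0.712849,
    "BN02_6": 0.734125,
    "BN03_1": 0.319314,
    "BN03_2": 0.521851,
    "BN03_3": 0.325865,
    "BN03_4": 0.506143,
    "BN03_5": 0.364472,
    "BN03_6": 0.568649,
    "BN04_1": 0.731174,
    "BN04_2": 0.190034,
    "BN04_3": 0.840904,
    "BN04_4": 0.830393,
    "BN04_5": 0.576247,
    "BN04_6": 0.457267
  },
  "treatment": {
    "BN01_1": "CFmove",
    "BN01_2": "CFmove",
    "BN01_3": "CFmove",
    "BN01_4": "CFstay",
    "BN01_5": "CFstay",
    "BN01_6": "CFstay",
    "BN02_1": "CFmove",
    "BN02_2": "CFmove",
    "BN02_3": "CFmove",
    "BN02_4": "CFstay",
    "BN02_5": "CFstay",
    "BN02_6": "CFstay",
    "BN03_1": "control",
    "BN03_2": "control",
    "BN03_3": "control",
    "BN03_4": "control",
    "BN03_5": "control",
    "BN03_6": "control",
    "BN04_1": "control",
    "BN04_2": "control",
    "BN04_3": "control",
    "BN04_4": "control",
    "BN04_5": "control",
    "BN04_6": "control"
  }
}
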