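{
  "species": "human",
  "body_weight_kg": 70.0,
  "tissues": {
    "lung":         {"volume_ml": 1170.0,  "blood_flow_ml_min": 5600.0,  "k_tp": 0.76},
    "heart":        {"volume_ml": 310.0,   "blood_flow_ml_min": 240.0,   "k_tp": 3.62},
    "brain":        {"volume_ml": 1450.0,  "blood_flow_ml_min": 700.0,   "k_tp": 4.16},
    "muscle":       {"volume_ml": 35000.0, "blood_flow_ml_min": 750.0,   "k_tp": 1.19},
    "adipose":      {"volume_ml": 10000.0, "blood_flow_ml_min": 260.0,   "k_tp": 2.84},
    "skin":         {"volume_ml": 7800.0,  "blood_flow_ml_min": 300.0,   "k_tp": 8.18},
    "kidney":       {"volume_ml": 280.0,   "blood_flow_ml_min": 1240.0,  "k_tp": 2.22},
    "spleen":       {"volume_ml": 190.0,   "blood_flow_ml_min": 80.0,    "k_tp": 1.27},
    "stomach":      {"volume_ml": 160.0,   "blood_flow_ml_min": 38.33,   "k_tp": 1.00},
    "liver":        {"volume_ml": 1690.0,  "blood_flow_ml_min": 1518.33, "k_tp": 2.06},
    "intestine":    {"volume_ml": 1650.0,  "blood_flow_ml_min": 1100.0,  "k_tp": 1.00},
    "rest_of_body": {"volume_ml": 5100.0,  "blood_flow_ml_min": 592.0,   "k_tp": 1.00},
    "vein":         {"volume_ml": 3470.0},
    "artery":       {"volume_ml": 1730.0}
  },
  "liver_arterial_flow_ml_min": 300.0,
  "mppgl": 48.8,
  "mppgk": 17.8,
  "mppgi": 0.54,
  "r_b": 0.92,
  "fu_p": 0.3264,
  "adipose_v1_ml": 1800.0,
  "adipose_v2_ml": 8200.0,
  "organ_weights_g_per_kg": {"liver": 25.7, "kidney": 4.39, "intestine": 14.4},
  "clearances": {
    "clint_u_ul_min_mg": {
      "liver": {"UGT": 745.0, "CYP": 3.35},
      "kidney": {"UGT": 339.0},
      "intestine": {"UGT": 39.8}
    },
    "ps_ml_min": null
  }
}
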