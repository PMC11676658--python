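{
  "species": "dog",
  "body_weight_kg": 8.5,
  "tissues": {
    "lung":         {"volume_ml": 85.0,   "blood_flow_ml_min": 1120.0, "k_tp": 0.62},
    "heart":        {"volume_ml": 43.0,   "blood_flow_ml_min": 43.3,   "k_tp": 0.76},
    "brain":        {"volume_ml": 50.0,   "blood_flow_ml_min": 145.0,  "k_tp": 1.44},
    "muscle":       {"volume_ml": 4250.0, "blood_flow_ml_min": 270.0,  "k_tp": 0.81},
    "adipose":      {"volume_ml": 1500.0, "blood_flow_ml_min": 50.0,   "k_tp": 1.72},
    "skin":         {"volume_ml": 774.0,  "blood_flow_ml_min": 71.5,   "k_tp": 6.46},
    "kidney":       {"volume_ml": 40.0,   "blood_flow_ml_min": 170.0,  "k_tp": 0.79},
    "spleen":       {"volume_ml": 22.0,   "blood_flow_ml_min": 13.33,  "k_tp": 0.49},
    "stomach":      {"volume_ml": 24.0,   "blood_flow_ml_min": 10.0,   "k_tp": 1.00},
    "liver":        {"volume_ml": 213.0,  "blood_flow_ml_min": 323.33, "k_tp": 0.81},
    "intestine":    {"volume_ml": 203.0,  "blood_flow_ml_min": 255.0,  "k_tp": 1.00},
    "rest_of_body": {"volume_ml": 871.0,  "blood_flow_ml_min": 48.33,  "k_tp": 1.00},
    "vein":         {"volume_ml": 284.0},
    "artery":       {"volume_ml": 141.0}
  },
  "liver_arterial_flow_ml_min": 45.0,
  "mppgl": 63.6,
  "mppgk": 44.0,
  "mppgi": 6.5,
  "r_b": 0.92,
  "fu_p": 0.2577,
  "adipose_v1_ml": 210.0,
  "adipose_v2_ml": 1290.0,
  "organ_weights_g_per_kg": {"liver": 32.9, "kidney": 5.50},
  "clearances": {
    "clint_u_ul_min_mg": {
      "liver": {"UGT": 12200.0, "CYP": 13.6},
      "kidney": {"UGT": 112.0},
      "intestine": {"UGT": 0.0}
    },
    "ps_ml_min": null
  }
}
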