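{
  "species": "rat",
  "body_weight_kg": 0.25,
  "tissues": {
    "lung": {
      "volume_ml": 1.25,
      "blood_flow_ml_min": 83.9,
      "k_tp": 0.59
    },
    "heart": {
      "volume_ml": 0.83,
      "blood_flow_ml_min": 4.07,
      "k_tp": 1.13
    },
    "brain": {
      "volume_ml": 1.43,
      "blood_flow_ml_min": 1.66,
      "k_tp": 1.46
    },
    "muscle": {
      "volume_ml": 117.5,
      "blood_flow_ml_min": 8.23,
      "k_tp": 0.9
    },
    "adipose": {
      "volume_ml": 19.0,
      "blood_flow_ml_min": 5.82,
      "k_tp": 1.92
    },
    "skin": {
      "volume_ml": 47.5,
      "blood_flow_ml_min": 4.82,
      "k_tp": 7.2
    },
    "kidney": {
      "volume_ml": 1.83,
      "blood_flow_ml_min": 11.71,
      "k_tp": 1.51
    },
    "spleen": {
      "volume_ml": 0.5,
      "blood_flow_ml_min": 1.66,
      "k_tp": 0.98
    },
    "stomach": {
      "volume_ml": 1.1,
      "blood_flow_ml_min": 1.13,
      "k_tp": 1.0
    },
    "liver": {
      "volume_ml": 9.15,
      "blood_flow_ml_min": 12.3,
      "k_tp": 1.53
    },
    "intestine": {
      "volume_ml": 10.01,
      "blood_flow_ml_min": 7.52,
      "k_tp": 1.0
    },
    "rest_of_body": {
      "volume_ml": 19.5,
      "blood_flow_ml_min": 35.29,
      "k_tp": 1.0
    },
    "vein": {
      "volume_ml": 13.6
    },
    "artery": {
      "volume_ml": 6.8
    }
  },
  "liver_arterial_flow_ml_min": 1.99,
  "mppgl": 44.8,
  "mppgk": 17.9,
  "mppgi": 9.7,
  "r_b": 1.1,
  "fu_p": 0.287,
  "adipose_v1_ml": 2.66,
  "adipose_v2_ml": 16.34,
  "organ_weights_g_per_kg": {
    "liver": 36.6,
    "intestine": 22.4
  },
  "clearances": {
    "clint_u_ul_min_mg": {
      "liver": {
        "UGT": 2060.0,
        "CYP": 5.14
      },
      "kidney": {
        "UGT": 1500.0
      },
      "intestine": {
        "UGT": 79.1
      }
    },
    "ps_ml_min": 0.7060834664682739
  }
}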