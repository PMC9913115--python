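{
  "new_magee_1": {
    "intercept": 15.31385,
    "weights": {
      "nottingham_score": 1.4055,
      "er_hscore": -0.01924,
      "pr_hscore": -0.02925,
      "tumor_size_cm": 0.78677,
      "ki67_percent": 0.13269
    },
    "her2_offsets": {"negative": 0.0, "equivocal": 0.77681, "positive": 11.58134},
    "required_variables": ["nottingham_score", "er_hscore", "pr_hscore", "tumor_size_cm", "ki67_percent"],
    "source": "New Magee equation 1 (University of Pittsburgh Magee-Womens Hospital linear models estimating the Oncotype DX recurrence score), evaluated here with Rochester modified ER/PR H-scores (dominant intensity x percent positive)"
  },
  "new_magee_2": {
    "intercept": 18.8042,
    "weights": {
      "nottingham_score": 2.1170,
      "er_hscore": -0.0287,
      "pr_hscore": -0.0261,
      "tumor_size_cm": 0.6043
    },
    "her2_offsets": {"negative": 0.0, "equivocal": 1.4055, "positive": 12.6680},
    "required_variables": ["nottingham_score", "er_hscore", "pr_hscore", "tumor_size_cm"],
    "source": "New Magee equation 2 (Ki-67-free form usable when a Ki-67 stain was not performed), with Rochester modified H-score inputs"
  },
  "new_magee_3": {
    "intercept": 15.2999,
    "weights": {
      "nottingham_score": 1.1587,
      "pr_hscore": -0.0121,
      "ki67_percent": 0.1486
    },
    "her2_offsets": {"negative": 0.0, "equivocal": 0.7974, "positive": 11.0601},
    "required_variables": ["nottingham_score", "pr_hscore", "ki67_percent"],
    "source": "New Magee equation 3 (no ER term or tumor size; usable on core biopsies), with Rochester modified H-score inputs"
  }
}
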