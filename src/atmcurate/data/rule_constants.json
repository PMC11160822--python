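{
  "schema_version": "1",
  "ba1_af": 0.005,
  "bs1_af": 0.0005,
  "pm2_af": 0.00001,
  "revel_hi": 0.733,
  "revel_lo": 0.249,
  "spliceai_hi": 0.2,
  "spliceai_lo": 0.1,
  "provean_deleterious_cutoff": -2.5,
  "bp7_donor_min_offset": 7,
  "bp7_acceptor_min_offset": -40,
  "ps4_or_min": 2.0,
  "ps4_p_max": 0.05,
  "ps4_ci_low_min": 1.5,
  "ps4_disjunctive": false,
  "pm3_point_table": {
    "confident": {
      "confirmed_in_trans": 4.0,
      "phase_unknown": 2.0,
      "vus_or_unidentified": 1.0,
      "homozygous": 2.0
    },
    "consistent": {
      "confirmed_in_trans": 2.0,
      "phase_unknown": 1.0,
      "vus_or_unidentified": 0.5,
      "homozygous": 1.0
    }
  },
  "pm3_strength_breaks": {
    "very_strong": 4.0,
    "strong": 2.0,
    "moderate": 1.0,
    "supporting": 0.5
  },
  "bp2_point_table": {
    "clinical_laboratory": {
      "confirmed_in_trans": -1.0,
      "phase_unknown": -0.5,
      "homozygous": -1.0
    },
    "database": {
      "confirmed_in_trans": -0.5,
      "phase_unknown": -0.25,
      "homozygous": -0.5
    }
  },
  "bp2_strength_breaks": {
    "strong": 4.0,
    "moderate": 2.0,
    "supporting": 1.0
  },
  "bp2_homozygous_cap": -2.0,
  "bp2_total_cap": -4.0,
  "nmd_window_nt": 50,
  "strength_points": {
    "supporting": 1.0,
    "moderate": 2.0,
    "strong": 4.0,
    "very_strong": 8.0
  },
  "point_tier_pathogenic_min": 10.0,
  "point_tier_likely_pathogenic_min": 6.0,
  "point_tier_likely_benign_max": -1.0,
  "point_tier_benign_max": -7.0
}
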