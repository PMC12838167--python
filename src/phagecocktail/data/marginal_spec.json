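{
  "panel_size": 156,
  "tolerance_pp": 0.2,
  "single_coverages": {
    "EPa2": 32.7,
    "EPa4": 31.4,
    "EPa5": 18.6,
    "EPa6": 46.2,
    "EPa7": 44.2,
    "EPa10": 40.4,
    "EPa11": 51.3,
    "EPa12": 46.2,
    "EPa13": 42.3,
    "EPa14": 42.3,
    "EPa15": 54.5,
    "EPa16": 35.9,
    "EPa17": 30.8,
    "EPa18": 37.8,
    "EPa20": 42.3,
    "EPa21": 39.7,
    "EPa22": 51.9,
    "EPa24": 46.8,
    "EPa25": 28.2,
    "EPa26": 42.9,
    "EPa33": 30.1,
    "EPa38": 7.7,
    "EPa39": 45.5,
    "EPa40": 32.7,
    "EPa43": 16.7
  },
  "pair_unions": {
    "EPa11+EPa16": 57.1,
    "EPa11+EPa17": 64.1,
    "EPa11+EPa22": 62.2,
    "EPa11+EPa24": 59.0,
    "EPa11+EPa40": 53.8,
    "EPa11+EPa43": 55.8,
    "EPa16+EPa17": 51.3,
    "EPa16+EPa22": 60.9,
    "EPa16+EPa24": 51.3,
    "EPa16+EPa40": 44.2,
    "EPa16+EPa43": 42.3,
    "EPa17+EPa22": 61.6,
    "EPa17+EPa24": 60.1,
    "EPa17+EPa40": 48.7,
    "EPa17+EPa43": 38.5,
    "EPa22+EPa24": 65.4,
    "EPa22+EPa40": 57.1,
    "EPa22+EPa43": 54.5,
    "EPa24+EPa40": 50.0,
    "EPa24+EPa43": 52.6,
    "EPa40+EPa43": 39.1
  },
  "set_unions": {
    "Mix-7": {
      "members": ["EPa11", "EPa16", "EPa17", "EPa22", "EPa24", "EPa40", "EPa43"],
      "percent": 78.2
    },
    "Mix-5": {
      "members": ["EPa11", "EPa17", "EPa22", "EPa24", "EPa43"],
      "percent": 76.3
    },
    "PAM1": {
      "members": ["EPa2", "EPa4", "EPa5", "EPa6", "EPa17"],
      "percent": 55.8
    },
    "all-lytic": {
      "members": ["EPa2", "EPa4", "EPa5", "EPa6", "EPa7", "EPa10", "EPa11",
                  "EPa12", "EPa13", "EPa14", "EPa15", "EPa16", "EPa17", "EPa18",
                  "EPa20", "EPa21", "EPa22", "EPa24", "EPa25", "EPa26", "EPa38",
                  "EPa39", "EPa40", "EPa43"],
      "percent": 85.3
    },
    "all-phages": {
      "members": ["EPa2", "EPa4", "EPa5", "EPa6", "EPa7", "EPa10", "EPa11",
                  "EPa12", "EPa13", "EPa14", "EPa15", "EPa16", "EPa17", "EPa18",
                  "EPa20", "EPa21", "EPa22", "EPa24", "EPa25", "EPa26", "EPa33",
                  "EPa38", "EPa39", "EPa40", "EPa43"],
      "percent": 85.3
    }
  }
}
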