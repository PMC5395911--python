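{
  "description": "Near-native pose counts per training complex (C1-C7) under successive screening stages of the ankyrin-protein docking benchmark: initial docking scored by shape complementarity alone (psc), by the composite score (psc_de_elec), after the recognition-area filter (regkp), and within the top-2000 poses ranked by ZRank (top2k).",
  "complexes": ["C1", "C2", "C3", "C4", "C5", "C6", "C7"],
  "near_native": {
    "psc":         [81, 4, 125, 83, 31, 84, 35],
    "psc_de_elec": [157, 72, 194, 131, 101, 42, 119],
    "regkp":       [136, 53, 179, 104, 59, 28, 110],
    "top2k":       [83, 19, 54, 74, 8, 18, 74]
  },
  "non_near_native_regkp": [6626, 4865, 7055, 4450, 8565, 6177, 6596]
}
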