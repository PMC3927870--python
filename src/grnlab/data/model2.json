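{
  "schema": "grnlab-model/1",
  "model_class": "protein_only",
  "_provenance": "Synthetic stand-in topology and parameters. The 11-gene / 16-regulation structure, the parameter census (16 synthesis + 16 Kd + 16 Hill + 11 degradation + 2 basal = 61), the two unregulated genes (g5, g11), one two-gene operon target, the three hidden links (r9, r10, r12) and the oscillatory wildtype dynamics follow the published challenge qualitatively; the exact wiring and values were never printed and these defaults are implementer-chosen. The g1-g2-g3 repression cycle (Hill coefficient 4) provides sustained oscillations; r12 targets the operon with a deliberately large Kd (17.9), making it hard to detect from data whose regulator stays below Kd.",
  "genes": [
    {"id": "g1", "operon_id": null},
    {"id": "g2", "operon_id": null},
    {"id": "g3", "operon_id": null},
    {"id": "g4", "operon_id": null},
    {"id": "g5", "operon_id": null},
    {"id": "g6", "operon_id": "op1"},
    {"id": "g7", "operon_id": "op1"},
    {"id": "g8", "operon_id": null},
    {"id": "g9", "operon_id": null},
    {"id": "g10", "operon_id": null},
    {"id": "g11", "operon_id": null}
  ],
  "regulations": [
    {"id": "r1", "source": "g1", "targets": ["g2"], "sign": "-"},
    {"id": "r2", "source": "g2", "targets": ["g3"], "sign": "-"},
    {"id": "r3", "source": "g3", "targets": ["g1"], "sign": "-"},
    {"id": "r4", "source": "g4", "targets": ["g6", "g7"], "sign": "+"},
    {"id": "r5", "source": "g5", "targets": ["g4"], "sign": "+"},
    {"id": "r6", "source": "g6", "targets": ["g8"], "sign": "-"},
    {"id": "r7", "source": "g7", "targets": ["g9"], "sign": "+"},
    {"id": "r8", "source": "g8", "targets": ["g10"], "sign": "+"},
    {"id": "r9", "source": "g9", "targets": ["g2"], "sign": "-"},
    {"id": "r10", "source": "g11", "targets": ["g8"], "sign": "+"},
    {"id": "r11", "source": "g10", "targets": ["g9"], "sign": "-"},
    {"id": "r12", "source": "g5", "targets": ["g6", "g7"], "sign": "+"},
    {"id": "r13", "source": "g1", "targets": ["g4"], "sign": "+"},
    {"id": "r14", "source": "g2", "targets": ["g10"], "sign": "+"},
    {"id": "r15", "source": "g4", "targets": ["g1"], "sign": "-"},
    {"id": "r16", "source": "g11", "targets": ["g3"], "sign": "-"}
  ],
  "parameters": {
    "r1_synthesis": 5.0, "r1_Kd": 1.0, "r1_h": 4.0,
    "r2_synthesis": 5.0, "r2_Kd": 1.0, "r2_h": 4.0,
    "r3_synthesis": 5.0, "r3_Kd": 1.0, "r3_h": 4.0,
    "r4_synthesis": 2.0, "r4_Kd": 1.5, "r4_h": 2.0,
    "r5_synthesis": 1.5, "r5_Kd": 2.0, "r5_h": 2.0,
    "r6_synthesis": 2.0, "r6_Kd": 1.0, "r6_h": 2.0,
    "r7_synthesis": 2.0, "r7_Kd": 1.2, "r7_h": 2.0,
    "r8_synthesis": 1.5, "r8_Kd": 1.0, "r8_h": 2.0,
    "r9_synthesis": 0.5, "r9_Kd": 1.0, "r9_h": 2.0,
    "r10_synthesis": 0.8, "r10_Kd": 1.5, "r10_h": 2.0,
    "r11_synthesis": 1.0, "r11_Kd": 1.0, "r11_h": 2.0,
    "r12_synthesis": 1.2, "r12_Kd": 17.9, "r12_h": 2.0,
    "r13_synthesis": 1.0, "r13_Kd": 1.5, "r13_h": 2.0,
    "r14_synthesis": 1.0, "r14_Kd": 1.2, "r14_h": 2.0,
    "r15_synthesis": 0.5, "r15_Kd": 2.0, "r15_h": 2.0,
    "r16_synthesis": 0.5, "r16_Kd": 1.5, "r16_h": 2.0,
    "g1_degradation": 0.5,
    "g2_degradation": 0.5,
    "g3_degradation": 0.5,
    "g4_degradation": 0.3,
    "g5_degradation": 0.4,
    "g6_degradation": 0.5,
    "g7_degradation": 0.6,
    "g8_degradation": 0.4,
    "g9_degradation": 0.5,
    "g10_degradation": 0.3,
    "g11_degradation": 0.2,
    "g5_basal": 0.8,
    "g11_basal": 0.4
  },
  "initial_conditions": {}
}
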