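{
  "schema": "grnlab-model/1",
  "model_class": "mrna_protein",
  "_provenance": "Synthetic stand-in topology and parameters. The 9-gene / 13-regulation structure and the parameter census (9 promoter + 9 RBS strengths, 13 Kd, 13 Hill, 1 shared protein degradation = 45) follow the published challenge; the exact wiring and the hidden gold-standard values were never printed and these defaults are implementer-chosen. Gene g6 is unregulated (basal transcription only), as needed for the steady-state initialisation recipes.",
  "genes": [
    {"id": "g1", "operon_id": null},
    {"id": "g2", "operon_id": null},
    {"id": "g3", "operon_id": null},
    {"id": "g4", "operon_id": null},
    {"id": "g5", "operon_id": null},
    {"id": "g6", "operon_id": null},
    {"id": "g7", "operon_id": null},
    {"id": "g8", "operon_id": null},
    {"id": "g9", "operon_id": null}
  ],
  "regulations": [
    {"id": "r1", "source": "g6", "targets": ["g1"], "sign": "+"},
    {"id": "r2", "source": "g1", "targets": ["g2"], "sign": "-"},
    {"id": "r3", "source": "g2", "targets": ["g3"], "sign": "+"},
    {"id": "r4", "source": "g3", "targets": ["g4"], "sign": "-"},
    {"id": "r5", "source": "g4", "targets": ["g5"], "sign": "+"},
    {"id": "r6", "source": "g5", "targets": ["g1"], "sign": "-"},
    {"id": "r7", "source": "g6", "targets": ["g7"], "sign": "+"},
    {"id": "r8", "source": "g7", "targets": ["g8"], "sign": "-"},
    {"id": "r9", "source": "g7", "targets": ["g5"], "sign": "+"},
    {"id": "r10", "source": "g8", "targets": ["g9"], "sign": "+"},
    {"id": "r11", "source": "g9", "targets": ["g2"], "sign": "-"},
    {"id": "r12", "source": "g9", "targets": ["g4"], "sign": "+"},
    {"id": "r13", "source": "g2", "targets": ["g8"], "sign": "-"}
  ],
  "parameters": {
    "g1_promoter": 2.0, "g1_rbs": 1.0,
    "g2_promoter": 1.5, "g2_rbs": 2.0,
    "g3_promoter": 3.0, "g3_rbs": 1.5,
    "g4_promoter": 1.0, "g4_rbs": 0.9,
    "g5_promoter": 2.5, "g5_rbs": 1.2,
    "g6_promoter": 1.2, "g6_rbs": 2.5,
    "g7_promoter": 0.8, "g7_rbs": 1.1,
    "g8_promoter": 2.0, "g8_rbs": 0.7,
    "g9_promoter": 1.8, "g9_rbs": 1.6,
    "r1_Kd": 1.5, "r1_h": 2.0,
    "r2_Kd": 2.0, "r2_h": 2.0,
    "r3_Kd": 1.0, "r3_h": 1.5,
    "r4_Kd": 0.8, "r4_h": 2.0,
    "r5_Kd": 1.2, "r5_h": 2.5,
    "r6_Kd": 2.5, "r6_h": 2.0,
    "r7_Kd": 1.8, "r7_h": 1.5,
    "r8_Kd": 1.0, "r8_h": 2.0,
    "r9_Kd": 0.6, "r9_h": 2.0,
    "r10_Kd": 1.4, "r10_h": 1.5,
    "r11_Kd": 2.2, "r11_h": 2.0,
    "r12_Kd": 0.9, "r12_h": 2.5,
    "r13_Kd": 1.1, "r13_h": 2.0,
    "protein_degradation_rate": 0.5
  },
  "initial_conditions": {}
}
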