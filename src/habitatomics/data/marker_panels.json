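{
  "_comment": "Compact marker panels for MCPcounter-style abundance indices. Synthetic composition of widely used canonical markers; the B-cell set combines lineage markers (CD19, CD79A, MS4A1) with immunoglobulin genes (IGHM, IGHG1, IGHG2).",
  "B": ["CD19", "CD79A", "MS4A1", "IGHM", "IGHG1", "IGHG2"],
  "T": ["CD3D", "CD3E", "CD2", "CD5"],
  "cytotoxic_lymphocyte": ["GZMB", "PRF1", "NKG7", "KLRK1"],
  "myeloid": ["CD68", "CD163", "CSF1R", "ITGAM"],
  "endothelial": ["PECAM1", "VWF", "CDH5"],
  "fibroblast": ["COL1A1", "COL1A2", "DCN", "PDGFRB"]
}
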