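{
  "description": "Default radiology concept graph over the 14 finding nodes: the clinical hierarchy grouping parenchymal opacities under lung_opacity, cardiac silhouette findings, and pleural findings. Edges are undirected; edit or replace to supply domain knowledge.",
  "nodes": [
    "atelectasis",
    "cardiomegaly",
    "consolidation",
    "edema",
    "enlarged_cardiomediastinum",
    "fracture",
    "lung_lesion",
    "lung_opacity",
    "pleural_effusion",
    "pleural_other",
    "pneumonia",
    "pneumothorax",
    "support_devices",
    "no_finding"
  ],
  "edges": [
    [7, 0],
    [7, 2],
    [7, 3],
    [7, 6],
    [7, 10],
    [2, 10],
    [4, 1],
    [8, 9]
  ]
}
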