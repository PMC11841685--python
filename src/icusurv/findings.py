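"""Canonical thorax-finding vocabulary.

Thirteen radiographic findings commonly labelled in ICU chest X-ray reports,
in a fixed order, plus a derived ``no_finding`` entry that is 1 exactly when
all thirteen disease indicators are 0 (14 labels total).
"""

DISEASES: tuple[str, ...] = (
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
)

NO_FINDING = "no_finding"

LABELS: tuple[str, ...] = DISEASES + (NO_FINDING,)

N_DISEASES = len(DISEASES)
N_LABELS = len(LABELS)
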