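"""Compartment vocabulary shared across the pipeline.

The partition model divides the body into four compartments: the tumor,
the in-target normal liver (parenchyma supplied by the treated artery),
the out-target normal liver (supplied by other arteries) and the lungs,
which receive activity through arteriovenous shunting. Label grids encode
them with small integer codes; 0 is background.
"""

from __future__ import annotations

TUMOR = "tumor"
IN_TARGET = "in_target_liver"
OUT_TARGET = "out_target_liver"
LUNG = "lung"

#: The three liver partitions that share the non-shunted activity.
LIVER_PARTITIONS = (TUMOR, IN_TARGET, OUT_TARGET)

#: All four partition-model compartments.
COMPARTMENTS = (TUMOR, IN_TARGET, OUT_TARGET, LUNG)

#: Integer codes used in label grids (0 = background).
LABEL_CODES = {TUMOR: 1, IN_TARGET: 2, OUT_TARGET: 3, LUNG: 4}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}

#: Tissue densities in kg/L: unit density for soft tissue (tumor and both
#: normal-liver partitions), 0.3 kg/L for aerated lung.
DENSITY_KG_PER_L = {TUMOR: 1.0, IN_TARGET: 1.0, OUT_TARGET: 1.0, LUNG: 0.3}
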