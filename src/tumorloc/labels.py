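"""Shared label and modality conventions.

The segmentation problem uses four co-registered MR modalities and integer
lesion labels {0, 1, 2, 4}.  Probability maps carry five classes in order
[0, 1, 2, 3, 4]; class 3 is a permanently-near-zero legacy channel kept so
that fusion feature vectors have a fixed five-class block per ensemble.
"""

from __future__ import annotations

MODALITIES: tuple[str, ...] = ("t1", "t1gd", "t2", "flair")

BACKGROUND = 0
ENHANCING_TUMOR = 1
EDEMA = 2
LEGACY = 3  # never emitted; kept for the fixed 5-class probability layout
NECROSIS_NET = 4

#: labels a ground-truth or predicted volume may contain
VALID_LABELS: tuple[int, ...] = (BACKGROUND, ENHANCING_TUMOR, EDEMA, NECROSIS_NET)

#: class order of every probability map (axis 0 index -> label)
CLASS_ORDER: tuple[int, ...] = (0, 1, 2, 3, 4)
N_CLASSES = len(CLASS_ORDER)

DEFAULT_LABEL_SEMANTICS: dict[int, str] = {
    BACKGROUND: "background",
    ENHANCING_TUMOR: "enhancing_tumor",
    EDEMA: "edema",
    NECROSIS_NET: "necrosis_non_enhancing_tumor",
}

#: Harvard-Oxford subcortical parcellation label table (21 regions)
HARVARD_OXFORD_SUBCORTICAL: dict[int, str] = {
    1: "Left Cerebral White Matter",
    2: "Left Cerebral Cortex",
    3: "Left Lateral Ventricle",
    4: "Left Thalamus",
    5: "Left Caudate",
    6: "Left Putamen",
    7: "Left Pallidum",
    8: "Brain-Stem",
    9: "Left Hippocampus",
    10: "Left Amygdala",
    11: "Left Accumbens",
    12: "Right Cerebral White Matter",
    13: "Right Cerebral Cortex",
    14: "Right Lateral Ventricle",
    15: "Right Thalamus",
    16: "Right Caudate",
    17: "Right Putamen",
    18: "Right Pallidum",
    19: "Right Hippocampus",
    20: "Right Amygdala",
    21: "Right Accumbens",
}


def label_to_class_index(labels):
    """Map a label array {0,1,2,4} to class indices {0,1,2,4} (identity here,
    since CLASS_ORDER is [0..4]); kept as a function so the convention lives
    in one place."""
    import numpy as np

    arr = np.asarray(labels)
    bad = set(np.unique(arr)) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected subset of {CLASS_ORDER}")
    return arr.astype(np.int64)
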