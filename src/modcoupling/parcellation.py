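"""Cerebrum-only 90-region parcellation and the packaged six-module reference.

The label list follows the standard automated anatomical labeling order for
the 90 cerebral regions (45 left/right pairs, cerebellum excluded).  The
module assignment groups those labels into six named functional systems with
sizes (18, 20, 17, 14, 10, 11).  The grouping is a coarse, synthetic stand-in
for a data-driven modular decomposition: it is anatomically plausible but was
drawn up by hand for simulation and labelling purposes, not estimated from
imaging data.
"""

from __future__ import annotations

import numpy as np

_BASE_NAMES = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

#: The 90 cerebral region labels, left/right interleaved.
AAL90_LABELS: list[str] = [
    f"{name}_{side}" for name in _BASE_NAMES for side in ("L", "R")
]

#: Canonical module order; ids 0..5 index this list everywhere.
MODULE_NAMES: tuple[str, ...] = (
    "Central", "DefaultMode", "Frontoparietal", "Occipital",
    "Subcortical", "Hippocampal",
)

DEFAULT_MODULE_SIZES: tuple[int, ...] = (18, 20, 17, 14, 10, 11)

_MODULE_REGIONS: dict[str, tuple[str, ...]] = {
    "Central": (
        "Precentral_L", "Precentral_R", "Rolandic_Oper_L", "Rolandic_Oper_R",
        "Supp_Motor_Area_L", "Supp_Motor_Area_R", "Insula_L", "Insula_R",
        "Cingulum_Mid_L", "Cingulum_Mid_R", "Postcentral_L", "Postcentral_R",
        "Paracentral_Lobule_L", "Paracentral_Lobule_R", "Heschl_L",
        "Heschl_R", "Temporal_Sup_L", "Temporal_Sup_R",
    ),
    "DefaultMode": (
        "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R", "Frontal_Mid_Orb_L",
        "Frontal_Mid_Orb_R", "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R",
        "Frontal_Med_Orb_L", "Frontal_Med_Orb_R", "Rectus_L", "Rectus_R",
        "Cingulum_Ant_L", "Cingulum_Ant_R", "Cingulum_Post_L",
        "Cingulum_Post_R", "Precuneus_L", "Precuneus_R", "Temporal_Mid_L",
        "Temporal_Mid_R", "Angular_R", "Temporal_Inf_R",
    ),
    "Frontoparietal": (
        "Frontal_Sup_L", "Frontal_Sup_R", "Frontal_Mid_L", "Frontal_Mid_R",
        "Frontal_Inf_Oper_L", "Frontal_Inf_Oper_R", "Frontal_Inf_Tri_L",
        "Frontal_Inf_Tri_R", "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
        "Parietal_Sup_L", "Parietal_Sup_R", "Parietal_Inf_L",
        "Parietal_Inf_R", "SupraMarginal_L", "SupraMarginal_R", "Angular_L",
    ),
    "Occipital": (
        "Calcarine_L", "Calcarine_R", "Cuneus_L", "Cuneus_R", "Lingual_L",
        "Lingual_R", "Occipital_Sup_L", "Occipital_Sup_R", "Occipital_Mid_L",
        "Occipital_Mid_R", "Occipital_Inf_L", "Occipital_Inf_R",
        "Fusiform_L", "Fusiform_R",
    ),
    "Subcortical": (
        "Olfactory_L", "Olfactory_R", "Caudate_L", "Caudate_R", "Putamen_L",
        "Putamen_R", "Pallidum_L", "Pallidum_R", "Thalamus_L", "Thalamus_R",
    ),
    "Hippocampal": (
        "Hippocampus_L", "Hippocampus_R", "ParaHippocampal_L",
        "ParaHippocampal_R", "Amygdala_L", "Amygdala_R",
        "Temporal_Pole_Sup_L", "Temporal_Pole_Sup_R", "Temporal_Pole_Mid_L",
        "Temporal_Pole_Mid_R", "Temporal_Inf_L",
    ),
}


def default_assignment() -> np.ndarray:
    """Module id (0..5, indexing :data:`MODULE_NAMES`) for each of the 90
    labels in :data:`AAL90_LABELS` order."""
    lookup = {
        label: mid
        for mid, name in enumerate(MODULE_NAMES)
        for label in _MODULE_REGIONS[name]
    }
    return np.array([lookup[label] for label in AAL90_LABELS], dtype=np.intp)


def module_members(name: str) -> tuple[str, ...]:
    """Region labels belonging to the named module."""
    return _MODULE_REGIONS[name]
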