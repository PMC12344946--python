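"""Reference summaries of a published 95-subject adult diffuse glioma cohort.

These are the group-level descriptive statistics and diagnostic operating
points of a multi-b-value DWI glioma study (52 IDH wild-type glioblastomas,
12 IDH-mutant 1p/19q non-codeleted astrocytomas, 31 IDH-mutant codeleted
oligodendrogliomas; 13 b-values 0-2000 s/mm², 30 directions).  They serve
two purposes:

* defaults for the synthetic cohort generator (:mod:`qdwi.simulate`), so
  that simulated parameter distributions match the clinically observed
  medians and IQRs;
* inputs to the confusion-matrix consistency checks, which reconstruct the
  published accuracies from the printed sensitivity/specificity and group
  sizes.

Diffusivities are in 1e-3 mm²/s.  Distribution entries are either
``("median_iqr", median, q1, q3)`` or ``("mean_sd", mean, sd)`` as printed.
"""

from __future__ import annotations

__all__ = ["GROUP_SIZES", "GROUP_SUMMARIES", "IDH_OPERATING_POINTS",
           "CODELETION_OPERATING_POINTS", "MORPHOLOGY_RATES",
           "IDH_HIGHER_IN_MUTANT", "CODELETION_LOWER_IN_CODELETED",
           "ICC_RANGE"]

GROUP_SIZES = {"idh-wild": 52, "mutant-noncodel": 12, "mutant-codel": 31}

#: per-group marginal distributions of the nine VOI-mean parameters
GROUP_SUMMARIES = {
    "idh-wild": {
        "Mono_ADC":   ("median_iqr", 1.088, 0.997, 1.219),
        "IVIM_D":     ("median_iqr", 0.983, 0.883, 1.083),
        "IVIM_Dstar": ("median_iqr", 7.298, 6.630, 7.929),
        "IVIM_f":     ("median_iqr", 0.089, 0.075, 0.106),
        "SEM_alpha":  ("median_iqr", 0.867, 0.840, 0.880),
        "SEM_DDC":    ("median_iqr", 1.117, 1.029, 1.274),
        "CTRW_alpha": ("median_iqr", 0.825, 0.789, 0.849),
        "CTRW_beta":  ("median_iqr", 0.938, 0.917, 0.956),
        "CTRW_Dm":    ("median_iqr", 1.218, 1.102, 1.365),
    },
    "mutant-noncodel": {
        "Mono_ADC":   ("median_iqr", 1.281, 1.193, 1.377),
        "IVIM_D":     ("mean_sd", 1.188, 0.159),
        "IVIM_Dstar": ("median_iqr", 7.399, 6.981, 9.730),
        "IVIM_f":     ("mean_sd", 0.087, 0.035),
        "SEM_alpha":  ("median_iqr", 0.874, 0.827, 0.911),
        "SEM_DDC":    ("median_iqr", 1.347, 1.288, 1.421),
        "CTRW_alpha": ("median_iqr", 0.894, 0.885, 0.906),
        "CTRW_beta":  ("median_iqr", 0.908, 0.880, 0.973),
        "CTRW_Dm":    ("median_iqr", 1.387, 1.364, 1.466),
    },
    "mutant-codel": {
        "Mono_ADC":   ("median_iqr", 1.188, 1.140, 1.238),
        "IVIM_D":     ("mean_sd", 1.089, 0.098),
        "IVIM_Dstar": ("median_iqr", 7.453, 6.991, 8.541),
        "IVIM_f":     ("mean_sd", 0.084, 0.028),
        "SEM_alpha":  ("median_iqr", 0.875, 0.839, 0.911),
        "SEM_DDC":    ("median_iqr", 1.210, 1.155, 1.272),
        "CTRW_alpha": ("median_iqr", 0.860, 0.836, 0.876),
        "CTRW_beta":  ("median_iqr", 0.937, 0.911, 0.967),
        "CTRW_Dm":    ("median_iqr", 1.309, 1.251, 1.348),
    },
}

#: published ROC operating points for predicting IDH status
#: (43 IDH-mutant positives vs 52 wild-type negatives):
#: parameter -> (threshold, auc, ci_lo, ci_hi, sensitivity, specificity,
#: accuracy)
IDH_OPERATING_POINTS = {
    "Mono_ADC":   (1.122, 0.737, 0.634, 0.839, 0.860, 0.673, 0.758),
    "IVIM_D":     (0.998, 0.750, 0.644, 0.843, 0.884, 0.654, 0.758),
    "IVIM_Dstar": (8.586, 0.592, 0.470, 0.707, 0.279, 0.904, 0.621),
    "IVIM_f":     (0.067, 0.568, 0.447, 0.686, 0.372, 0.865, 0.642),
    "SEM_alpha":  (0.896, 0.584, 0.456, 0.703, 0.419, 0.904, 0.684),
    "SEM_DDC":    (1.130, 0.728, 0.623, 0.826, 0.907, 0.577, 0.726),
    "CTRW_alpha": (0.855, 0.761, 0.661, 0.854, 0.651, 0.846, 0.758),
    "CTRW_beta":  (0.909, 0.511, 0.388, 0.634, 0.326, 0.846, 0.611),
    "CTRW_Dm":    (1.248, 0.694, 0.585, 0.793, 0.791, 0.596, 0.684),
}

#: published ROC operating points for predicting 1p/19q status within
#: IDH-mutant gliomas (12 non-codeleted positives vs 31 codeleted negatives)
CODELETION_OPERATING_POINTS = {
    "Mono_ADC":   (1.250, 0.704, 0.503, 0.882, 0.667, 0.774, 0.744),
    "IVIM_D":     (1.134, 0.683, 0.465, 0.866, 0.667, 0.806, 0.767),
    "IVIM_Dstar": (9.357, 0.554, 0.344, 0.750, 0.333, 0.935, 0.767),
    "IVIM_f":     (0.100, 0.508, 0.306, 0.712, 0.417, 0.742, 0.651),
    "SEM_alpha":  (0.853, 0.505, 0.290, 0.731, 0.500, 0.677, 0.628),
    "SEM_DDC":    (1.265, 0.750, 0.556, 0.917, 0.833, 0.742, 0.767),
    "CTRW_alpha": (0.886, 0.790, 0.613, 0.941, 0.750, 0.903, 0.860),
    "CTRW_beta":  (0.893, 0.583, 0.344, 0.801, 0.500, 0.903, 0.791),
    "CTRW_Dm":    (1.353, 0.731, 0.532, 0.898, 0.833, 0.806, 0.814),
}

#: per-group rates of the morphology flags (fraction of subjects with the
#: feature) and the location distribution
MORPHOLOGY_RATES = {
    "idh-wild": {
        "cystic_necrosis": 44 / 52, "hemorrhage": 4 / 52, "edema": 42 / 52,
        "enhancement": 47 / 52,
        "location": {"frontal-insula": 18, "basal-thalamus": 6, "other": 28},
    },
    "mutant-noncodel": {
        "cystic_necrosis": 7 / 12, "hemorrhage": 0.0, "edema": 7 / 12,
        "enhancement": 5 / 12,
        "location": {"frontal-insula": 9, "basal-thalamus": 0, "other": 3},
    },
    "mutant-codel": {
        "cystic_necrosis": 21 / 31, "hemorrhage": 0.0, "edema": 17 / 31,
        "enhancement": 13 / 31,
        "location": {"frontal-insula": 22, "basal-thalamus": 1, "other": 9},
    },
}

#: parameters reported significantly higher in IDH-mutant than wild-type
IDH_HIGHER_IN_MUTANT = ("Mono_ADC", "IVIM_D", "SEM_DDC", "CTRW_alpha",
                        "CTRW_Dm")

#: parameters reported significantly lower in 1p/19q-codeleted than
#: non-codeleted (within IDH-mutant)
CODELETION_LOWER_IN_CODELETED = ("SEM_DDC", "CTRW_alpha", "CTRW_Dm")

#: reported interobserver agreement range across all parameters
ICC_RANGE = (0.918, 0.996)
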