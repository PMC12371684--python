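"""Published summary counts for a newly-diagnosed focal epilepsy cohort.

These group-level counts and moments (104 patients, 45 controls) are the
published inputs for re-deriving the reported comparison p-values with
this package's test implementations: 2x2 contingency counts as
``[[control_yes, control_no], [patient_yes, patient_no]]`` and the age
comparison as per-group (n, mean, SD).
"""

from __future__ import annotations

#: 2x2 counts: rows (control, patient), columns (yes, no).
CONTINGENCY_2X2 = {
    "mri_conclusion_abnormal": [[20, 25], [64, 40]],
    "unknown_single_lesion": [[15, 30], [51, 53]],
    "unknown_multiple_lesions": [[1, 44], [15, 89]],
    "white_matter_hyperintensities": [[11, 34], [41, 63]],
    "flags_depression": [[4, 41], [51, 53]],
    "flags_anxiety": [[3, 42], [56, 48]],
    "flags_executive_function": [[1, 44], [19, 85]],
    "flags_processing_speed": [[0, 45], [13, 91]],
    "flags_visual_rt_m": [[1, 44], [18, 86]],
    "flags_delayed_memory": [[1, 44], [15, 89]],
    "flags_immediate_memory": [[0, 45], [9, 95]],
    "sex_male": [[24, 21], [57, 47]],
}

#: Published p-values for the rows above (3-decimal rounding).
PUBLISHED_P = {
    "mri_conclusion_abnormal": 0.053,
    "unknown_single_lesion": 0.076,
    "unknown_multiple_lesions": 0.027,
    "white_matter_hyperintensities": 0.078,
    "flags_executive_function": 0.008,
    "flags_processing_speed": 0.013,
    "flags_visual_rt_m": 0.011,
    "flags_delayed_memory": 0.027,
    "flags_immediate_memory": 0.042,
    "sex_male": 0.868,
}

#: Per-group age moments: (n, mean, SD); published comparison p = .052.
AGE_SUMMARY = {
    "control": (45, 40.752, 15.745),
    "patient": (104, 35.777, 13.526),
}
AGE_PUBLISHED_P = 0.052
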