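"""Published reference values from a 15-patient 7 T glioblastoma NOE-CEST study.

The voxelwise MTR_asym-vs-ADC Spearman coefficients per patient and ROI
(``TABLE1``) and the biopsy cellularity correlations of the three patients
who underwent stereotactic biopsy (``TABLE2``) are shipped as data so the
classification bookkeeping can be reproduced without the original images,
which were never deposited.

p-values were published as thresholds; ``p_from_label`` maps each label to
a representative numeric value on the correct side of every decision
boundary used by the classification (0.05 and 0.001).
"""

from __future__ import annotations

import pandas as pd

P_LABELS = {"<0.001": 0.0005, "<0.05": 0.01, ">0.05": 0.5}


def p_from_label(label: str) -> float:
    """Numeric stand-in for a thresholded published p-value."""
    return P_LABELS[label]


# patient, r (CE-T1), p label, n voxels (CE-T1), r (T2 edema), p label, n voxels
_TABLE1_ROWS = [
    (1, -0.07, ">0.05", 658, 0.09, "<0.001", 2577),
    (2, -0.17, "<0.05", 316, 0.16, "<0.001", 1083),
    (3, 0.02, ">0.05", 325, 0.18, "<0.05", 198),
    (4, 0.06, ">0.05", 98, 0.20, "<0.001", 851),
    (5, 0.04, ">0.05", 242, 0.20, "<0.001", 1077),
    (6, 0.00, ">0.05", 1515, 0.23, "<0.001", 3044),
    (7, 0.19, "<0.001", 1931, 0.26, "<0.001", 1254),
    (8, -0.10, "<0.05", 663, 0.29, "<0.001", 3759),
    (9, 0.28, "<0.001", 713, 0.53, "<0.001", 2366),
    (10, 0.12, "<0.001", 1662, -0.07, "<0.001", 3261),
    (11, -0.31, "<0.001", 1967, -0.13, "<0.05", 414),
    (12, 0.07, "<0.05", 916, 0.03, ">0.05", 1269),
    (13, 0.07, "<0.05", 2172, 0.03, ">0.05", 1203),
    (14, 0.13, "<0.001", 1720, -0.01, ">0.05", 1080),
    (15, -0.01, ">0.05", 225, -0.04, ">0.05", 170),
]

TABLE1 = pd.DataFrame(
    _TABLE1_ROWS,
    columns=[
        "patient",
        "r_ce_t1",
        "p_ce_t1_label",
        "n_ce_t1",
        "r_t2_edema",
        "p_t2_edema_label",
        "n_t2_edema",
    ],
)
TABLE1["p_ce_t1"] = TABLE1["p_ce_t1_label"].map(P_LABELS)
TABLE1["p_t2_edema"] = TABLE1["p_t2_edema_label"].map(P_LABELS)

# patient, r(MTR_asym, cell density), p, r(ADC, cell density), p,
# number of biopsies, maximum cell density (cells/mm^3)
_TABLE2_ROWS = [
    (3, 0.685, 0.014, 0.545, 0.067, 12, 9699.0),
    (4, 0.126, 0.697, -0.021, 0.948, 12, 3293.0),
    (15, 0.867, 0.0005, -0.755, 0.005, 12, 17256.0),
]

TABLE2 = pd.DataFrame(
    _TABLE2_ROWS,
    columns=[
        "patient",
        "r_mtr_cell",
        "p_mtr_cell",
        "r_adc_cell",
        "p_adc_cell",
        "n_biopsies",
        "max_cell_density",
    ],
)
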