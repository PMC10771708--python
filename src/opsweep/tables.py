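"""Reference-cohort calibration constants.

The package's synthetic cohort is calibrated to a published 903-patient
orthodontic reference cohort: the 3x3 (sagittal x vertical) cell allocation
with per-sex counts, per-cell means and standard deviations of the sixteen
cephalometric indicators, and the per-cell linear coefficients (slope k,
intercept b) of the two aesthetic indices FHR and FA against SN-OP.

Units: linear measures in mm, angles in degrees, FHR in percent (0-100).
"""

from __future__ import annotations

import numpy as np

SAGITTAL = ("I", "II", "III")
VERTICAL = ("hypo", "nor", "hyper")

#: canonical cell order used by every per-cell table in this module
CELLS: tuple[tuple[str, str], ...] = tuple((s, v) for s in SAGITTAL for v in VERTICAL)

#: the ten surrogate input features, SN_OP last by convention
INPUT_FEATURES = (
    "N_ANS", "S_N", "SNA", "NA_FH", "Ptm_A", "PP_FH",
    "Go_Po", "Go_Co", "S_Go", "SN_OP",
)

#: additional indicators sampled directly by the generator (classification axes)
CLASSIFIER_FEATURES = ("SN_MP", "FH_MP", "ANB")

#: every generated / validated numeric indicator, canonical column order
ALL_FIELDS = (
    "N_ANS", "S_N", "Ptm_A", "SNA", "NA_FH", "PP_FH",
    "Go_Po", "Go_Co", "S_Go", "SN_OP",
    "FHR", "FA", "SNB", "ANB", "FH_MP", "SN_MP",
)

MM_FIELDS = ("N_ANS", "S_N", "Ptm_A", "Go_Po", "Go_Co", "S_Go")

# per-cell per-sex allocation of the reference cohort: cell -> (female, male)
CELL_ALLOCATION: dict[tuple[str, str], tuple[int, int]] = {
    ("I", "hypo"): (62, 40),
    ("I", "nor"): (67, 42),
    ("I", "hyper"): (63, 43),
    ("II", "hypo"): (52, 33),
    ("II", "nor"): (65, 42),
    ("II", "hyper"): (62, 39),
    ("III", "hypo"): (62, 41),
    ("III", "nor"): (64, 39),
    ("III", "hyper"): (53, 34),
}

TOTAL_N = 903
TOTAL_FEMALE = 550
TOTAL_MALE = 353

# per-cell (mean, sd) of each indicator; keys follow ALL_FIELDS minus the two
# modelled outcomes' dependence (FHR/FA rows are the observed reference
# moments, used for plausibility bounds, not sampled directly)
FEATURE_STATS: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "N_ANS": {
        ("I", "hypo"): (51.9, 3.2), ("I", "nor"): (52.4, 3.5), ("I", "hyper"): (53.0, 3.3),
        ("II", "hypo"): (53.1, 4.3), ("II", "nor"): (52.5, 3.0), ("II", "hyper"): (53.1, 3.2),
        ("III", "hypo"): (52.7, 2.9), ("III", "nor"): (52.8, 3.3), ("III", "hyper"): (53.5, 3.5),
    },
    "S_N": {
        ("I", "hypo"): (63.1, 3.7), ("I", "nor"): (63.2, 4.2), ("I", "hyper"): (63.0, 3.3),
        ("II", "hypo"): (64.3, 4.1), ("II", "nor"): (63.2, 4.1), ("II", "hyper"): (62.7, 3.8),
        ("III", "hypo"): (64.0, 4.2), ("III", "nor"): (63.8, 4.1), ("III", "hyper"): (63.0, 3.8),
    },
    "Ptm_A": {
        ("I", "hypo"): (45.5, 3.2), ("I", "nor"): (44.1, 3.5), ("I", "hyper"): (43.6, 3.4),
        ("II", "hypo"): (47.6, 3.7), ("II", "nor"): (46.0, 3.4), ("II", "hyper"): (45.1, 2.8),
        ("III", "hypo"): (44.8, 3.1), ("III", "nor"): (44.1, 3.9), ("III", "hyper"): (42.4, 3.2),
    },
    "SNA": {
        ("I", "hypo"): (82.3, 2.7), ("I", "nor"): (80.1, 2.3), ("I", "hyper"): (78.6, 3.2),
        ("II", "hypo"): (83.8, 2.3), ("II", "nor"): (82.2, 3.1), ("II", "hyper"): (80.9, 2.8),
        ("III", "hypo"): (81.6, 3.3), ("III", "nor"): (80.0, 3.1), ("III", "hyper"): (77.3, 2.9),
    },
    "NA_FH": {
        ("I", "hypo"): (91.6, 3.0), ("I", "nor"): (90.8, 2.6), ("I", "hyper"): (89.5, 2.4),
        ("II", "hypo"): (92.2, 2.9), ("II", "nor"): (92.2, 2.5), ("II", "hyper"): (91.5, 3.3),
        ("III", "hypo"): (90.1, 2.9), ("III", "nor"): (89.8, 2.9), ("III", "hyper"): (87.9, 2.3),
    },
    "PP_FH": {
        ("I", "hypo"): (0.1, 3.0), ("I", "nor"): (0.9, 2.6), ("I", "hyper"): (1.0, 2.8),
        ("II", "hypo"): (1.0, 2.5), ("II", "nor"): (0.6, 2.9), ("II", "hyper"): (1.0, 3.2),
        ("III", "hypo"): (0.9, 2.7), ("III", "nor"): (0.8, 3.5), ("III", "hyper"): (1.5, 3.0),
    },
    "Go_Po": {
        ("I", "hypo"): (72.6, 5.0), ("I", "nor"): (71.7, 5.0), ("I", "hyper"): (70.6, 4.5),
        ("II", "hypo"): (70.0, 5.2), ("II", "nor"): (69.2, 4.6), ("II", "hyper"): (67.9, 4.3),
        ("III", "hypo"): (75.7, 4.6), ("III", "nor"): (74.2, 5.8), ("III", "hyper"): (74.2, 4.5),
    },
    "Go_Co": {
        ("I", "hypo"): (59.9, 4.3), ("I", "nor"): (56.3, 4.3), ("I", "hyper"): (53.2, 4.3),
        ("II", "hypo"): (60.3, 5.0), ("II", "nor"): (55.7, 3.7), ("II", "hyper"): (52.3, 4.5),
        ("III", "hypo"): (60.9, 5.0), ("III", "nor"): (58.8, 4.9), ("III", "hyper"): (54.6, 3.7),
    },
    "S_Go": {
        ("I", "hypo"): (79.2, 5.8), ("I", "nor"): (74.2, 5.0), ("I", "hyper"): (70.4, 5.9),
        ("II", "hypo"): (79.8, 7.0), ("II", "nor"): (73.8, 4.3), ("II", "hyper"): (69.8, 5.6),
        ("III", "hypo"): (80.4, 6.3), ("III", "nor"): (77.0, 6.2), ("III", "hyper"): (71.9, 4.2),
    },
    "SN_OP": {
        ("I", "hypo"): (13.7, 3.8), ("I", "nor"): (17.8, 3.0), ("I", "hyper"): (19.9, 3.1),
        ("II", "hypo"): (16.1, 3.2), ("II", "nor"): (18.4, 3.8), ("II", "hyper"): (21.9, 3.5),
        ("III", "hypo"): (11.2, 3.7), ("III", "nor"): (14.7, 4.0), ("III", "hyper"): (17.5, 4.2),
    },
    "FHR": {
        ("I", "hypo"): (70.1, 3.0), ("I", "nor"): (64.4, 1.0), ("I", "hyper"): (60.4, 2.5),
        ("II", "hypo"): (69.3, 2.6), ("II", "nor"): (64.3, 1.5), ("II", "hyper"): (59.8, 2.7),
        ("III", "hypo"): (70.8, 3.3), ("III", "nor"): (65.8, 1.7), ("III", "hyper"): (60.9, 2.0),
    },
    "FA": {
        ("I", "hypo"): (89.4, 2.7), ("I", "nor"): (88.2, 2.8), ("I", "hyper"): (86.7, 2.5),
        ("II", "hypo"): (86.8, 2.7), ("II", "nor"): (86.3, 2.7), ("II", "hyper"): (84.5, 3.5),
        ("III", "hypo"): (92.2, 2.5), ("III", "nor"): (91.3, 3.2), ("III", "hyper"): (89.5, 2.8),
    },
    "FH_MP": {
        ("I", "hypo"): (18.0, 3.6), ("I", "nor"): (24.0, 3.4), ("I", "hyper"): (29.0, 3.8),
        ("II", "hypo"): (21.7, 3.5), ("II", "nor"): (25.8, 3.5), ("II", "hyper"): (32.1, 4.8),
        ("III", "hypo"): (17.5, 3.4), ("III", "nor"): (23.0, 3.1), ("III", "hyper"): (27.6, 3.4),
    },
    "SN_MP": {
        ("I", "hypo"): (27.3, 3.7), ("I", "nor"): (34.7, 2.5), ("I", "hyper"): (40.0, 3.2),
        ("II", "hypo"): (30.1, 3.5), ("II", "nor"): (35.8, 3.1), ("II", "hyper"): (42.7, 4.3),
        ("III", "hypo"): (26.0, 3.4), ("III", "nor"): (32.8, 2.7), ("III", "hyper"): (38.2, 3.6),
    },
    "SNB": {
        ("I", "hypo"): (79.1, 2.6), ("I", "nor"): (76.9, 2.3), ("I", "hyper"): (75.4, 3.3),
        ("II", "hypo"): (77.7, 2.3), ("II", "nor"): (76.0, 3.2), ("II", "hyper"): (74.0, 3.0),
        ("III", "hypo"): (82.6, 3.7), ("III", "nor"): (81.0, 3.6), ("III", "hyper"): (78.4, 3.5),
    },
    "ANB": {
        ("I", "hypo"): (3.2, 0.9), ("I", "nor"): (3.2, 1.1), ("I", "hyper"): (3.2, 1.1),
        ("II", "hypo"): (6.1, 0.8), ("II", "nor"): (6.2, 1.0), ("II", "hyper"): (6.9, 1.5),
        ("III", "hypo"): (-1.0, 1.9), ("III", "nor"): (-0.9, 1.9), ("III", "hyper"): (-1.1, 1.8),
    },
}

# per-cell (k, b) of the linear response of each outcome to SN-OP
FHR_COEFFICIENTS: dict[tuple[str, str], tuple[float, float]] = {
    ("I", "hypo"): (-0.28, 73.07), ("I", "nor"): (-0.28, 70.14), ("I", "hyper"): (-0.28, 66.97),
    ("II", "hypo"): (-0.27, 72.97), ("II", "nor"): (-0.28, 70.12), ("II", "hyper"): (-0.29, 67.74),
    ("III", "hypo"): (-0.26, 72.61), ("III", "nor"): (-0.28, 70.73), ("III", "hyper"): (-0.27, 66.97),
}

FA_COEFFICIENTS: dict[tuple[str, str], tuple[float, float]] = {
    ("I", "hypo"): (-0.40, 95.47), ("I", "nor"): (-0.31, 94.21), ("I", "hyper"): (-0.25, 91.45),
    ("II", "hypo"): (-0.37, 94.42), ("II", "nor"): (-0.32, 93.14), ("II", "hyper"): (-0.23, 90.63),
    ("III", "hypo"): (-0.47, 96.78), ("III", "nor"): (-0.41, 96.07), ("III", "hyper"): (-0.34, 94.72),
}

#: grand-mean FHR slope of the reference cohort (percent per degree)
MEAN_FHR_SLOPE = -0.28


def cell_count(cell: tuple[str, str]) -> int:
    f, m = CELL_ALLOCATION[cell]
    return f + m


def cell_weights() -> np.ndarray:
    """Reference allocation proportions in CELLS order."""
    counts = np.array([cell_count(c) for c in CELLS], dtype=float)
    return counts / counts.sum()


def pooled_moments(field: str) -> tuple[float, float]:
    """Allocation-weighted pooled mean and total SD of one indicator.

    The total SD combines within-cell variance and between-cell spread of
    the means; used for plausibility windows and noise scaling.
    """
    w = cell_weights()
    stats = FEATURE_STATS[field]
    means = np.array([stats[c][0] for c in CELLS])
    sds = np.array([stats[c][1] for c in CELLS])
    mu = float(w @ means)
    var = float(w @ (sds**2 + means**2) - mu**2)
    return mu, float(np.sqrt(max(var, 0.0)))
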