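"""Reported reference values from the pecan kernel-development study design
this pipeline targets.

``MARKER_IONS`` are the observed m/z values of the Car i 1 (2S albumin) and
Car i 2 (7S vicilin) marker peptide ions, with carbamidomethyl-Cys
throughout and N-terminal pyroglutamate where noted; observed values sit
within the +-20 ppm instrument tolerance of theory.

``TABLE_DEVELOPMENT`` and ``TABLE_CULTIVAR`` are the reported differential
2-D gel spot tables: per spot, the mean spot percentages of the four
(cultivar x time point) cells, the reported t-test p-value and the reported
signed fold change. The development table compares the dough stage (9/18)
with the maturing kernel (9/25) pooling cultivars; the cultivar table
compares Sumner with Desirable pooling time points. Both come from a gel
series with 1267 detected spots, which sets the abundance floor
0.25 x 100 / 1267.
"""

from __future__ import annotations

import pandas as pd

from .masses import ModificationSet

#: (peptide, charge, mods, observed m/z, allergen, reported apex RT in minutes)
MARKER_IONS = [
    ("QCCQQLSQMEEQCQCEGLR", 3, ModificationSet(), 824.6703, "Car i 1", 6.5),
    ("QCCQQLSQMEEQCQCEGLR", 2, ModificationSet(), 1236.5175, "Car i 1", 6.5),
    (
        "QQQQEEGIRGEEMEEMVQCASDLPK",
        3,
        ModificationSet(pyroglutamate=True),
        978.0988,
        "Car i 1",
        15.5,
    ),
    ("NFLAGQNNIINQLER", 2, ModificationSet(), 872.4482, "Car i 2", 15.8),
    ("VFSNDILVAALNTPR", 2, ModificationSet(), 815.4394, "Car i 2", 17.8),
]

#: Total spots detected in the gel series the tables come from.
N_SPOTS_REPORTED = 1267

_DEV_ROWS = [
    # spot, pI, MW, Sumner 9/18, Desirable 9/18, Sumner 9/25, Desirable 9/25, p, fold
    (1009, 5.5, 26026, 0.062, 0.040, 0.014, 0.010, 0.009, -4.2),
    (1028, 6.7, 25239, 0.051, 0.060, 0.016, 0.020, 0.001, -3.1),
    (1151, 6.0, 19065, 0.060, 0.092, 0.029, 0.027, 0.006, -2.7),
    (862, 5.7, 32037, 0.086, 0.096, 0.182, 0.214, 0.000, 2.2),
    (610, 4.7, 42287, 0.040, 0.046, 0.111, 0.102, 0.004, 2.5),
    (715, 5.3, 37991, 0.014, 0.011, 0.032, 0.032, 0.002, 2.5),
    (178, 5.4, 84412, 0.069, 0.062, 0.142, 0.206, 0.003, 2.7),
    (269, 5.7, 74076, 0.022, 0.020, 0.053, 0.066, 0.007, 2.8),
    (821, 5.9, 33630, 0.026, 0.018, 0.053, 0.087, 0.011, 3.2),
    (636, 5.2, 41401, 0.010, 0.008, 0.037, 0.030, 0.005, 3.7),
    (1054, 5.9, 23850, 0.027, 0.030, 0.113, 0.140, 0.002, 4.4),
    (705, 5.3, 38408, 0.004, 0.006, 0.014, 0.029, 0.012, 4.5),
]

_CULT_ROWS = [
    # spot, pI, MW, Sumner 9/18, Sumner 9/25, Desirable 9/18, Desirable 9/25, p, fold
    (1065, 5.8, 23464, 0.047, 0.045, 0.009, 0.007, 0.000, -5.9),
    (882, 5.5, 31051, 0.036, 0.028, 0.016, 0.009, 0.018, -2.6),
    (428, 5.6, 57373, 0.020, 0.021, 0.006, 0.010, 0.001, -2.5),
    (502, 6.2, 51081, 0.013, 0.006, 0.034, 0.025, 0.001, 3.0),
    (710, 6.4, 38215, 0.036, 0.030, 0.104, 0.112, 0.000, 3.3),
    (1130, 4.6, 20193, 0.004, 0.003, 0.022, 0.018, 0.000, 5.5),
    (955, 5.4, 27814, 0.012, 0.005, 0.072, 0.044, 0.004, 6.7),
    (244, 6.4, 76898, 0.011, 0.011, 0.034, 0.114, 0.040, 6.9),
    (839, 6.1, 32868, 0.016, 0.006, 0.100, 0.087, 0.000, 8.6),
    (966, 5.7, 27524, 0.006, 0.007, 0.070, 0.052, 0.000, 9.4),
    (942, 6.3, 28302, 0.005, 0.004, 0.059, 0.054, 0.000, 12.7),
]


def _frame(rows, cell_names):
    return pd.DataFrame(
        rows,
        columns=["spot", "pI", "MW", *cell_names, "p_reported", "fold_reported"],
    ).set_index("spot")


#: Dough stage (9/18, group 1 cells) vs maturing kernel (9/25, group 2 cells).
TABLE_DEVELOPMENT = _frame(
    _DEV_ROWS,
    ["Sumner_Sep18", "Desirable_Sep18", "Sumner_Sep25", "Desirable_Sep25"],
)
DEVELOPMENT_GROUP1 = ["Sumner_Sep18", "Desirable_Sep18"]
DEVELOPMENT_GROUP2 = ["Sumner_Sep25", "Desirable_Sep25"]

#: Sumner (group 1 cells) vs Desirable (group 2 cells).
TABLE_CULTIVAR = _frame(
    _CULT_ROWS,
    ["Sumner_Sep18", "Sumner_Sep25", "Desirable_Sep18", "Desirable_Sep25"],
)
CULTIVAR_GROUP1 = ["Sumner_Sep18", "Sumner_Sep25"]
CULTIVAR_GROUP2 = ["Desirable_Sep18", "Desirable_Sep25"]
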