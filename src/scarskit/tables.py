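"""Transcribed count-table fixtures: the printed population parameters,
overlap counts and statistics of the published enrichment and overlap tables
this pipeline reproduces (identified here as T1–T6).

Enrichment rows carry the full hypergeometric quadruple (N, K, n, k) plus the
printed p value and observed/expected ratio; count rows carry
(total, overlap, printed percent).  The printed p values follow the
point-probability convention P(X = k) (see ``enrichment.hypergeom_overlap_test``),
which ``reproduce-tables`` verifies digit-for-digit.

Only printed numbers are transcribed; dataset-dependent quantities that
cannot be recomputed at desk scale (e.g. the 9,430 up-regulated genes
themselves) enter solely as fixture parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EnrichmentFixtureRow",
    "CountFixtureRow",
    "ENRICHMENT_ROWS",
    "COUNT_ROWS",
    "STEMNESS_COUNTS",
    "STEMNESS_PRINTED_TOTALS",
    "STEMNESS_FAMILY_COUNT",
]


@dataclass(frozen=True)
class EnrichmentFixtureRow:
    table_id: str
    row_label: str
    N: int
    K: int
    n: int
    k: int
    printed_percent: str  # printed at 1 dp
    printed_p: str
    printed_oe: str  # printed at 2 dp


@dataclass(frozen=True)
class CountFixtureRow:
    table_id: str
    row_label: str
    total: int
    overlap: int
    printed_percent: str  # printed at 2 dp


# T1 — lineage-marker enrichment among genes up-regulated in MLME cells:
# background 26,178 analyzed genes, 9,430 up-regulated.
_T1 = [
    ("EPI markers", 100, 91, "91.0", "1.186E-30", "2.53"),
    ("PE markers", 88, 41, "46.6", "0.0107581", "1.29"),
    ("TE markers", 100, 81, "81.0", "2.799E-20", "2.25"),
]

# T6 — embryonic-lineage expression signatures within hESC active-enhancer
# regulatory networks: background 63,677 genome genes; network sizes
# naive 18,766, primed 17,131, combined 25,421.
_T6_NETWORKS = {"naive": 18766, "primed": 17131, "naive+primed": 25421}
_T6 = [
    ("Human EPI vs naive hESC", 1496, "naive", 762, "50.9", "1.544E-69", "1.73"),
    ("Human EPI vs naive hESC", 1496, "primed", 726, "48.5", "5.669E-73", "1.80"),
    ("Human EPI vs naive hESC", 1496, "naive+primed", 976, "65.2", "4.326E-89", "1.63"),
    ("Human EPI vs TE", 836, "naive", 525, "62.8", "1.176E-89", "2.13"),
    ("Human EPI vs TE", 836, "primed", 472, "56.5", "2.095E-73", "2.10"),
    ("Human EPI vs TE", 836, "naive+primed", 647, "77.4", "2.11E-109", "1.94"),
    ("Monkey EPI", 719, "naive", 442, "61.5", "1.665E-71", "2.09"),
    ("Monkey EPI", 719, "primed", 399, "55.5", "1.687E-59", "2.06"),
    ("Monkey EPI", 719, "naive+primed", 529, "73.6", "1.003E-75", "1.84"),
    ("Mouse ICM vs TE", 497, "naive", 246, "49.5", "2.533E-21", "1.68"),
    ("Mouse ICM vs TE", 497, "primed", 211, "42.5", "2.314E-14", "1.58"),
    ("Mouse ICM vs TE", 497, "naive+primed", 303, "61.0", "1.061E-21", "1.53"),
]

ENRICHMENT_ROWS: list[EnrichmentFixtureRow] = [
    EnrichmentFixtureRow("T1", label, 26178, 9430, n, k, pct, p, oe)
    for label, n, k, pct, p, oe in _T1
] + [
    EnrichmentFixtureRow(
        "T6", f"{sig} | {net}", 63677, _T6_NETWORKS[net], n, k, pct, p, oe
    )
    for sig, n, net, k, pct, p, oe in _T6
]


# T2 — SCARS-regulated fractions of the 13,824 HSRS-associated genes.
_T2 = [
    ("HERV-H lncRNA-regulated", 4805, "34.76"),
    ("LTR7Y/B enhancers-regulated", 5240, "37.91"),
    ("LTR5_Hs/SVA_D enhancers-regulated", 2022, "14.63"),
    ("All SCARS-regulated HSRS-associated", 8384, "60.65"),
]

# T3 — HSRS-associated fractions of cancer survival predictor genes per type.
_T3 = [
    ("Thyroid", 347, 269, "77.52"),
    ("Glioma", 271, 206, "76.01"),
    ("Melanoma", 205, 153, "74.63"),
    ("Head and neck", 808, 597, "73.89"),
    ("Colorectal", 603, 440, "72.97"),
    ("Renal", 6070, 4418, "72.78"),
    ("Ovarian", 504, 366, "72.62"),
    ("Liver", 2892, 2086, "72.13"),
    ("Lung", 662, 477, "72.05"),
    ("Breast", 582, 414, "71.13"),
    ("Urothelial", 1101, 783, "71.12"),
    ("Stomach", 307, 218, "71.01"),
    ("Prostate", 161, 114, "70.81"),
    ("Endometrial", 1631, 1153, "70.69"),
    ("Cervical", 717, 505, "70.43"),
    ("Pancreatic", 1549, 1075, "69.40"),
    ("Testis", 60, 42, "70.00"),
    ("ALL", 10713, 7738, "72.23"),
]

# T4 — SCARS-regulated (and per-family) fractions of cancer survival genes.
# Each printed percent cell becomes one row: label = "<cancer>|<regulator>".
_T4_RAW = [
    ("Breast", 582, 405, "69.59", 229, "39.35", 284, "48.80", 80, "13.75"),
    ("Prostate", 161, 121, "75.16", 63, "39.13", 90, "55.90", 10, "6.21"),
    ("Pancreatic", 1549, 1112, "71.79", 629, "40.61", 772, "49.84", 250, "16.14"),
    ("Liver", 2892, 2217, "76.66", 1267, "43.81", 1565, "54.11", 382, "13.21"),
    ("Renal", 6070, 4406, "72.59", 2579, "42.49", 2881, "47.46", 965, "15.90"),
    ("Colorectal", 603, 448, "74.30", 262, "43.45", 320, "53.07", 104, "17.25"),
    ("Cervical", 717, 526, "73.36", 312, "43.51", 340, "47.42", 112, "15.62"),
    ("Lung", 662, 488, "73.72", 298, "45.02", 312, "47.13", 105, "15.86"),
    ("Thyroid", 347, 259, "74.64", 153, "44.09", 171, "49.28", 56, "16.14"),
    ("Ovarian", 504, 368, "73.02", 202, "40.08", 233, "46.23", 78, "15.48"),
    ("Endometrial", 1631, 1129, "69.22", 652, "39.98", 747, "45.80", 250, "15.33"),
    ("Urothelial", 1101, 772, "70.12", 458, "41.60", 483, "43.87", 164, "14.90"),
    ("Head & neck", 808, 558, "69.06", 340, "42.08", 369, "45.67", 128, "15.84"),
    ("Glioma", 271, 204, "75.28", 115, "42.44", 128, "47.23", 48, "17.71"),
    ("Melanoma", 205, 148, "72.20", 85, "41.46", 107, "52.20", 25, "12.20"),
    ("Stomach", 307, 219, "71.34", 144, "46.91", 131, "42.67", 25, "8.14"),
    ("Testis", 60, 41, "68.33", 23, "38.33", 26, "43.33", 11, "18.33"),
    ("ALL", 10713, 7609, "71.03", 4436, "41.41", 5013, "46.79", 1641, "15.32"),
]

_T4_FAMILIES = ("SCARS", "HERV-H", "LTR7Y/B", "LTR5_Hs/SVA_D")

COUNT_ROWS: list[CountFixtureRow] = (
    [CountFixtureRow("T2", label, 13824, k, pct) for label, k, pct in _T2]
    + [CountFixtureRow("T3", label, total, k, pct) for label, total, k, pct in _T3]
    + [
        CountFixtureRow("T4", f"{label}|{fam}", total, row[2 * i + 2], row[2 * i + 3])
        for row in _T4_RAW
        for label, total in [(row[0], row[1])]
        for i, fam in enumerate(_T4_FAMILIES)
    ]
)


# T5 — stemness-matrix gene counts: cancer type -> (silenced, activated)
# driver genes, crossed with 3 regulator families to give node counts.
STEMNESS_COUNTS: dict[str, tuple[int, int]] = {
    "Adenoid Cystic": (7, 4),
    "Bladder": (30, 16),
    "Blood": (25, 22),
    "Brain": (28, 16),
    "Breast": (28, 17),
    "Cervix": (12, 8),
    "Cholangiocarcinoma": (8, 4),
    "Colorectal": (16, 12),
    "Endometrium": (30, 20),
    "Gastroesophageal": (37, 26),
    "Head & Neck": (19, 6),
    "Kidney Clear": (8, 5),
    "Kidney Non-Clear": (14, 6),
    "Liver": (18, 10),
    "Lung AD": (15, 9),
    "Lung SC": (7, 3),
    "Lymph": (36, 25),
    "Ovarian": (4, 2),
    "Pancreas": (22, 17),
    "Pheochromocytoma": (5, 3),
    "Pleura": (9, 0),
    "Prostate": (19, 11),
    "Sarcoma": (6, 3),
    "Skin": (21, 13),
    "Testicular Germ Cell": (11, 8),
    "Thymus": (7, 2),
    "Thyroid": (8, 9),
    "Uveal Melanoma": (2, 1),
}

# Printed bold node totals (silenced, activated).  The silenced total does
# not equal the silenced column sum × 3 as transcribed (1,365 vs 1,356); the
# activated one does (834 = 278 × 3).  reproduce-tables reports this as a
# consistency note rather than resolving it.
STEMNESS_PRINTED_TOTALS = (1365, 834)
STEMNESS_FAMILY_COUNT = 3
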