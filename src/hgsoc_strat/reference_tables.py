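"""Published association tables for the TCGA high-grade serous ovarian
cancer cohort (n = 541 with both calls available).

These are the printed cross-tabulations of the two-group transcriptomic
classification (non-Fibrosis / Fibrosis), the four-group D-I-M-P
classification, and the genomic LST classification (LST-low / LST-high)
against clinical parameters, together with the p-values as printed.  They
serve as fixed input data for reproducing the Fisher-exact association
layer of the pipeline; counts are patients, rows are variable levels,
columns are the classification groups.

``printed_p`` is the published value and ``ulp`` one unit in its last
printed digit (the resolution at which agreement can be asserted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ContingencyTable


@dataclass(frozen=True)
class PublishedTable:
    key: str
    classification: str
    variable: str
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]
    printed_p: float
    ulp: float

    def table(self) -> ContingencyTable:
        return ContingencyTable(
            list(self.row_labels), list(self.col_labels),
            np.array(self.counts, dtype=np.int64),
        )


_FIB = ("non_Fibrosis", "Fibrosis")
_DIMP = ("D", "I", "M", "P")
_LST = ("LST_low", "LST_high")

PUBLISHED_TABLES: list[PublishedTable] = [
    # --- Fibrosis / non-Fibrosis classification vs clinical parameters ---
    PublishedTable("fibrosis_grade", "fibrosis", "grade", ("G2", "G3"), _FIB,
                   ((32, 25), (245, 170)), 0.67, 0.01),
    PublishedTable("fibrosis_stage", "fibrosis", "stage", ("II", "III-IV"), _FIB,
                   ((20, 4), (260, 195)), 0.01, 0.01),
    PublishedTable("fibrosis_debulking", "fibrosis", "debulking",
                   ("full", "partial"), _FIB, ((60, 28), (190, 149)), 0.05, 0.01),
    PublishedTable("fibrosis_platinum", "fibrosis", "platinum_resistance",
                   ("sensitive", "resistant"), _FIB,
                   ((153, 99), (49, 40)), 0.38, 0.01),
    PublishedTable("fibrosis_therapy_outcome", "fibrosis",
                   "primary_therapy_outcome", ("complete", "partial"), _FIB,
                   ((172, 101), (59, 59)), 0.02, 0.01),
    PublishedTable("fibrosis_brca_mutation", "fibrosis", "brca1_2_mutation",
                   ("no", "yes"), _FIB, ((269, 171), (49, 46)), 0.11, 0.01),
    PublishedTable("fibrosis_brca1_methylation", "fibrosis",
                   "brca1_methylation", ("no", "yes"), _FIB,
                   ((278, 190), (40, 27)), 1.0, 0.01),
    PublishedTable("fibrosis_rad51c_methylation", "fibrosis",
                   "rad51c_methylation", ("no", "yes"), _FIB,
                   ((312, 210), (6, 7)), 0.39, 0.01),
    PublishedTable("fibrosis_lst", "fibrosis", "lst_signature",
                   ("low", "high"), _FIB, ((147, 89), (171, 127)), 0.29, 0.01),
    PublishedTable("fibrosis_ploidy", "fibrosis", "ploidy",
                   ("2", ">=4"), _FIB, ((104, 83), (214, 133)), 0.20, 0.01),
    # --- D-I-M-P classification vs clinical parameters (2 x 4 tables) ---
    PublishedTable("dimp_grade", "dimp", "grade", ("G2", "G3"), _DIMP,
                   ((13, 9, 17, 18), (116, 93, 83, 116)), 0.28, 0.01),
    PublishedTable("dimp_stage", "dimp", "stage", ("II", "III-IV"), _DIMP,
                   ((5, 12, 1, 6), (129, 92, 101, 126)), 0.007, 0.001),
    PublishedTable("dimp_debulking", "dimp", "debulking",
                   ("full", "partial"), _DIMP,
                   ((33, 17, 10, 28), (90, 70, 81, 91)), 0.03, 0.01),
    PublishedTable("dimp_platinum", "dimp", "platinum_resistance",
                   ("sensitive", "resistant"), _DIMP,
                   ((70, 54, 53, 73), (30, 15, 18, 25)), 0.70, 0.01),
    PublishedTable("dimp_therapy_outcome", "dimp", "primary_therapy_outcome",
                   ("complete", "partial"), _DIMP,
                   ((78, 60, 49, 85), (34, 27, 30, 25)), 0.15, 0.01),
    PublishedTable("dimp_brca_mutation", "dimp", "brca1_2_mutation",
                   ("no", "yes"), _DIMP,
                   ((118, 103, 94, 124), (30, 26, 24, 14)), 0.05, 0.01),
    PublishedTable("dimp_brca1_methylation", "dimp", "brca1_methylation",
                   ("no", "yes"), _DIMP,
                   ((127, 110, 101, 128), (21, 19, 17, 10)), 0.15, 0.01),
    PublishedTable("dimp_rad51c_methylation", "dimp", "rad51c_methylation",
                   ("no", "yes"), _DIMP,
                   ((144, 124, 115, 137), (4, 5, 3, 1)), 0.38, 0.01),
    PublishedTable("dimp_lst", "dimp", "lst_signature", ("low", "high"), _DIMP,
                   ((62, 43, 48, 82), (86, 86, 70, 56)), 0.0002, 0.0001),
    PublishedTable("dimp_ploidy", "dimp", "ploidy", ("2", ">=4"), _DIMP,
                   ((71, 39, 46, 31), (77, 90, 72, 107)), 4.6e-5, 0.1e-5),
    # --- LST genomic classification vs clinical parameters ---
    PublishedTable("lst_grade", "lst", "grade", ("G2", "G3"), _LST,
                   ((27, 30), (189, 224)), 0.89, 0.01),
    PublishedTable("lst_stage", "lst", "stage", ("II", "III-IV"), _LST,
                   ((8, 16), (210, 243)), 0.29, 0.01),
    PublishedTable("lst_debulking", "lst", "debulking", ("full", "partial"),
                   _LST, ((39, 51), (158, 177)), 0.55, 0.01),
    PublishedTable("lst_platinum", "lst", "platinum_resistance",
                   ("sensitive", "resistant"), _LST,
                   ((71, 124), (55, 34)), 0.0001, 0.0001),
    PublishedTable("lst_therapy_outcome", "lst", "primary_therapy_outcome",
                   ("complete", "partial"), _LST,
                   ((111, 164), (59, 58)), 0.07, 0.01),
    PublishedTable("lst_brca_mutation", "lst", "brca1_2_mutation",
                   ("no", "yes"), _LST, ((229, 217), (9, 86)), 2.0e-15, 0.1e-15),
    PublishedTable("lst_brca1_methylation", "lst", "brca1_methylation",
                   ("no", "yes"), _LST, ((238, 235), (0, 68)), 1.9e-19, 0.1e-19),
    PublishedTable("lst_rad51c_methylation", "lst", "rad51c_methylation",
                   ("no", "yes"), _LST, ((238, 290), (0, 13)), 0.0008, 0.0001),
    PublishedTable("lst_fibrosis", "lst", "transcriptomic_signature",
                   ("non_Fibrosis", "Fibrosis"), _LST,
                   ((147, 171), (89, 127)), 0.29, 0.01),
    PublishedTable("lst_ploidy", "lst", "ploidy", ("2", ">=4"), _LST,
                   ((41, 150), (197, 153)), 2.7e-15, 0.1e-15),
]
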