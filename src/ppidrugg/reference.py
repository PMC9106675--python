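"""Published benchmark values for the 12-target PPI druggability survey.

These are the reported per-target median descriptor values of a curated set
of 320 crystal structures covering 12 frequently targeted protein-protein
interactions (DCN1/UBC12, Bcl-xL/BAD/BAK, HDM2/p53, XDM2/p53, Bcl-2/Bax,
MDMX/p53, HPV E2/E1, Menin/MLL, VHL/HIF-1a, IL-2/IL-2Ra, XIAP/Smac and
ZipA/FtsZ).  They serve three purposes:

* validation inputs for the Dscore arithmetic and the classification
  boundaries;
* generator parameters for the synthetic emulation of the survey;
* expected classes for the two classification schemes.

``None`` marks values not reported (ZipA has a flat, pocket-less interface:
no site was detected for any of its structures, so all its descriptor
entries are ND).
"""

from __future__ import annotations

__all__ = [
    "TARGET_MEDIANS",
    "FORM_MEDIANS",
    "EXPECTED_PPI_CLASS",
    "EXPECTED_HALGREN_CLASS",
    "FORMULA_CONSISTENT_TARGETS",
    "PERCENT_REDUCTION_CASES",
]

#: Overall per-target medians: reported median Dscore and median site
#: descriptors (n, e, p) with the reported min-max ranges, plus the number
#: of crystal structures surveyed.
TARGET_MEDIANS: dict[str, dict] = {
    "DCN1":   {"count": 10, "dscore": 1.20, "dscore_range": (1.14, 1.25), "n": 98, "n_range": (85, 110), "e": 0.75, "e_range": (0.71, 0.83), "p": 0.53, "p_range": (0.46, 0.66)},
    "Bcl-xL": {"count": 24, "dscore": 1.01, "dscore_range": (0.38, 1.17), "n": 46, "n_range": (9, 194),  "e": 0.71, "e_range": (0.62, 0.94), "p": 0.49, "p_range": (0.12, 1.17)},
    "HDM2":   {"count": 87, "dscore": 1.00, "dscore_range": (0.82, 1.33), "n": 54, "n_range": (20, 105), "e": 0.66, "e_range": (0.55, 0.82), "p": 0.28, "p_range": (0.10, 0.52)},
    "XDM2":   {"count": 11, "dscore": 0.93, "dscore_range": (0.83, 1.08), "n": 49, "n_range": (27, 57),  "e": 0.64, "e_range": (0.62, 0.73), "p": 0.35, "p_range": (0.12, 0.41)},
    "Bcl-2":  {"count": 26, "dscore": 0.92, "dscore_range": (0.74, 1.19), "n": 46, "n_range": (20, 104), "e": 0.67, "e_range": (0.58, 0.78), "p": 0.32, "p_range": (0.15, 0.53)},
    "MDMX":   {"count": 21, "dscore": 0.86, "dscore_range": (0.76, 1.19), "n": 40, "n_range": (28, 109), "e": 0.64, "e_range": (0.58, 0.72), "p": 0.33, "p_range": (0.06, 0.56)},
    "HPV E2": {"count": 2,  "dscore": 0.77, "dscore_range": (0.70, 0.84), "n": 44, "n_range": (41, 46),  "e": 0.68, "e_range": (0.66, 0.70), "p": 0.79, "p_range": (0.59, 0.99)},
    "Menin":  {"count": 34, "dscore": 0.77, "dscore_range": (0.43, 1.02), "n": 48, "n_range": (17, 100), "e": 0.72, "e_range": (0.64, 0.79), "p": 0.97, "p_range": (0.71, 1.13)},
    "VHL":    {"count": 36, "dscore": 0.68, "dscore_range": (0.33, 0.79), "n": 38, "n_range": (8, 52),   "e": 0.60, "e_range": (0.56, 0.64), "p": 0.82, "p_range": (0.57, 1.19)},
    "IL-2":   {"count": 14, "dscore": 0.60, "dscore_range": (0.35, 0.80), "n": 24, "n_range": (10, 55),  "e": 0.59, "e_range": (0.51, 0.80), "p": 0.67, "p_range": (0.43, 1.15)},
    "XIAP":   {"count": 49, "dscore": 0.52, "dscore_range": (0.23, 0.93), "n": 27, "n_range": (17, 80),  "e": 0.60, "e_range": (0.50, 0.67), "p": 1.01, "p_range": (0.72, 1.59)},
    "ZipA":   {"count": 6,  "dscore": None, "dscore_range": None,         "n": None, "n_range": None,    "e": None, "e_range": None,         "p": None, "p_range": None},
}

#: Per-crystal-form medians (+/- sample SD where reported): median Dscore
#: and median pocket size for apo, protein/peptide-bound and ligand-bound
#: structures of each target.  ``None`` marks forms without structures or
#: statistics not reported for single-structure forms.
FORM_MEDIANS: dict[str, dict[str, dict]] = {
    "DCN1": {
        "protein_peptide_bound": {"count": 2,  "dscore": 1.15, "dscore_sd": 0.01, "n": 96,   "n_sd": 4.24},
        "ligand_bound":          {"count": 8,  "dscore": 1.21, "dscore_sd": 0.03, "n": 98,   "n_sd": 7.87},
    },
    "Bcl-xL": {
        "apo":                   {"count": 4,  "dscore": 0.73, "dscore_sd": 0.29, "n": 19,   "n_sd": 8.73},
        "protein_peptide_bound": {"count": 4,  "dscore": 0.87, "dscore_sd": 0.10, "n": 32.5, "n_sd": 5.94},
        "ligand_bound":          {"count": 16, "dscore": 1.09, "dscore_sd": 0.09, "n": 140,  "n_sd": 63.82},
    },
    "HDM2": {
        "apo":                   {"count": 12, "dscore": 0.93, "dscore_sd": None, "n": 42,   "n_sd": None},
        "protein_peptide_bound": {"count": 26, "dscore": 0.97, "dscore_sd": 0.06, "n": 52,   "n_sd": 11.11},
        "ligand_bound":          {"count": 64, "dscore": 1.03, "dscore_sd": 0.11, "n": 55,   "n_sd": 16.35},
    },
    "XDM2": {
        "protein_peptide_bound": {"count": 1,  "dscore": 0.85, "dscore_sd": None, "n": 27,   "n_sd": None},
        "ligand_bound":          {"count": 10, "dscore": 0.93, "dscore_sd": 0.08, "n": 50.5, "n_sd": 7.84},
    },
    "Bcl-2": {
        "protein_peptide_bound": {"count": 9,  "dscore": 0.84, "dscore_sd": 0.06, "n": 30,   "n_sd": 11.86},
        "ligand_bound":          {"count": 17, "dscore": 0.97, "dscore_sd": 0.10, "n": 50,   "n_sd": 17.00},
    },
    "MDMX": {
        "protein_peptide_bound": {"count": 11, "dscore": 0.90, "dscore_sd": 0.07, "n": 40,   "n_sd": 7.27},
        "ligand_bound":          {"count": 10, "dscore": 0.85, "dscore_sd": 0.13, "n": 36.5, "n_sd": 24.70},
    },
    "HPV E2": {
        "apo":                   {"count": 1,  "dscore": 0.70, "dscore_sd": None, "n": 41,   "n_sd": None},
        "ligand_bound":          {"count": 1,  "dscore": 0.84, "dscore_sd": None, "n": 46,   "n_sd": None},
    },
    "Menin": {
        "apo":                   {"count": 1,  "dscore": 0.79, "dscore_sd": None, "n": 45,   "n_sd": None},
        "protein_peptide_bound": {"count": 4,  "dscore": 0.88, "dscore_sd": 0.10, "n": 71,   "n_sd": 19.16},
        "ligand_bound":          {"count": 29, "dscore": 0.76, "dscore_sd": 0.10, "n": 46,   "n_sd": 17.20},
    },
    "VHL": {
        "protein_peptide_bound": {"count": 5,  "dscore": 0.62, "dscore_sd": 0.13, "n": 29,   "n_sd": 13.20},
        "ligand_bound":          {"count": 31, "dscore": 0.69, "dscore_sd": 0.10, "n": 39,   "n_sd": 10.62},
    },
    "IL-2": {
        "apo":                   {"count": 4,  "dscore": 0.48, "dscore_sd": 0.19, "n": 21.5, "n_sd": 6.85},
        "protein_peptide_bound": {"count": 4,  "dscore": 0.48, "dscore_sd": 0.07, "n": 19.5, "n_sd": 6.70},
        "ligand_bound":          {"count": 6,  "dscore": 0.72, "dscore_sd": 0.12, "n": 30.5, "n_sd": 13.02},
    },
    "XIAP": {
        "apo":                   {"count": 2,  "dscore": 0.31, "dscore_sd": 0.11, "n": 17,   "n_sd": 0.0},
        "protein_peptide_bound": {"count": 15, "dscore": 0.52, "dscore_sd": 0.04, "n": 26,   "n_sd": 4.26},
        "ligand_bound":          {"count": 32, "dscore": 0.52, "dscore_sd": 0.14, "n": 28,   "n_sd": 16.35},
    },
    "ZipA": {
        "apo":                   {"count": 1,  "dscore": None, "dscore_sd": None, "n": None, "n_sd": None},
        "protein_peptide_bound": {"count": 1,  "dscore": None, "dscore_sd": None, "n": None, "n_sd": None},
        "ligand_bound":          {"count": 4,  "dscore": None, "dscore_sd": None, "n": None, "n_sd": None},
    },
}

#: Reported classes under the four-class PPI scheme (classified from the
#: overall median Dscore; ND targets are difficult).
EXPECTED_PPI_CLASS: dict[str, str] = {
    "DCN1": "very druggable",
    "Bcl-xL": "very druggable",
    "HDM2": "very druggable",
    "XDM2": "druggable",
    "Bcl-2": "druggable",
    "MDMX": "druggable",
    "HPV E2": "druggable",
    "Menin": "druggable",
    "VHL": "moderately druggable",
    "IL-2": "moderately druggable",
    "XIAP": "moderately druggable",
    "ZipA": "difficult",
}

#: Classes the same targets receive under Halgren's general scheme.
#: HDM2 is listed as druggable here: its unrounded score-of-medians (0.996)
#: falls below the very-druggable cutoff even though the reported median
#: rounds to 1.00.
EXPECTED_HALGREN_CLASS: dict[str, str] = {
    "DCN1": "very druggable",
    "Bcl-xL": "very druggable",
    "HDM2": "druggable",
    "XDM2": "druggable",
    "Bcl-2": "druggable",
    "MDMX": "druggable",
    "HPV E2": "difficult",
    "Menin": "difficult",
    "VHL": "difficult",
    "IL-2": "difficult",
    "XIAP": "difficult",
}

#: Targets whose reported median Dscore equals the score evaluated at the
#: reported component medians (to the printed two decimals).  Bcl-xL and
#: DCN1 are excluded: for skewed samples the median of scores need not
#: equal the score of medians, and their reported values differ.
FORMULA_CONSISTENT_TARGETS = ("HDM2", "XDM2", "XIAP", "Menin", "IL-2")

#: Reported apo / protein-bound Dscore reductions relative to the
#: ligand-bound median: (target, reference form, other form, percent).
PERCENT_REDUCTION_CASES = (
    ("Bcl-xL", "ligand_bound", "apo", 33),
    ("XIAP", "ligand_bound", "apo", 40),
    ("IL-2", "ligand_bound", "apo", 33),
    ("Bcl-xL", "ligand_bound", "protein_peptide_bound", 20),
)
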