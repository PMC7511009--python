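"""Published reference values from the EEC-SNS whiting survey.

These are the printed summary values of the whiting (*Merlangius merlangus*)
survey in the Eastern English Channel and Southern North Sea (autumn 2017
CGFS / winter 2018 IBTS; dataset deposited at doi:10.17882/72233). They serve
two purposes: as the default study structure for the synthetic-data generator
(sample sizes, size classes, per-cell trophic levels) and as inputs to
internal-consistency checks on the published tables.
"""

from __future__ import annotations

#: Size-class labels, 5-cm bins of total length; left-closed, right-open.
SIZE_CLASS_LABELS = ("10-15cm", "15-20cm", "20-25cm", "25-30cm", "30-35cm", "35+")

#: Lower edges of the size classes in mm; the last class is open above.
CLASS_EDGES_MM = (100.0, 150.0, 200.0, 250.0, 300.0, 350.0)

#: Maximum fish total length observed in the survey (mm); used as the upper
#: bound when drawing synthetic lengths in the open 35+ class.
MAX_LENGTH_MM = 530.0

SEASONS = ("autumn", "winter")

#: Number of stomachs analysed (SCA) per season and size class. No whiting
#: below 15 cm was caught in winter, so that cell is absent.
N_SCA = {
    ("autumn", "10-15cm"): 20,
    ("autumn", "15-20cm"): 19,
    ("autumn", "20-25cm"): 22,
    ("autumn", "25-30cm"): 20,
    ("autumn", "30-35cm"): 24,
    ("autumn", "35+"): 19,
    ("winter", "15-20cm"): 33,
    ("winter", "20-25cm"): 23,
    ("winter", "25-30cm"): 23,
    ("winter", "30-35cm"): 31,
    ("winter", "35+"): 14,
}

#: Number of muscle samples analysed for stable isotopes (SIA) per cell.
N_SIA = {
    ("autumn", "10-15cm"): 16,
    ("autumn", "15-20cm"): 18,
    ("autumn", "20-25cm"): 18,
    ("autumn", "25-30cm"): 18,
    ("autumn", "30-35cm"): 22,
    ("autumn", "35+"): 15,
    ("winter", "15-20cm"): 28,
    ("winter", "20-25cm"): 21,
    ("winter", "25-30cm"): 21,
    ("winter", "30-35cm"): 21,
    ("winter", "35+"): 14,
}

#: Published per-cell mean trophic level (Post equation, TL_B=2, TDF=3.4).
TL_BY_CELL = {
    ("autumn", "10-15cm"): 3.86,
    ("autumn", "15-20cm"): 4.06,
    ("autumn", "20-25cm"): 4.40,
    ("autumn", "25-30cm"): 4.40,
    ("autumn", "30-35cm"): 4.33,
    ("autumn", "35+"): 4.10,
    ("winter", "15-20cm"): 4.74,
    ("winter", "20-25cm"): 4.47,
    ("winter", "25-30cm"): 4.38,
    ("winter", "30-35cm"): 4.34,
    ("winter", "35+"): 4.34,
}

#: Baseline (queen scallop, *Aequipecten opercularis*) muscle δ¹⁵N summary:
#: 76 measurements, mean 7.69 ‰, SD 0.90 ‰.
BASELINE_N = 76
BASELINE_MEAN_D15N = 7.69
BASELINE_SD_D15N = 0.90

#: Published vacuity rates (% of empty stomachs) per season.
VACUITY_PCT = {"autumn": 16.0, "winter": 7.0}

#: Muscle C:N summary: mean 3.19, SD 0.08, range [3.08, 3.43].
CN_MEAN = 3.19
CN_SD = 0.08

#: The six prey groups of the diet analysis.
PREY_GROUPS = (
    "fish",
    "benthic_crustacean",
    "pelagic_crustacean",
    "unidentified_crustacean",
    "mollusk",
    "other",
)
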