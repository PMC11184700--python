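"""Reference cohort summary: printed group statistics of a pediatric
case-control study of trunk-muscle composition on opportunistic low-dose
chest CT (20 children with osteogenesis imperfecta, 40 age- and sex-matched
controls).

These summaries are *inputs*: the demo cohort generator reproduces their
group moments exactly, and the summary-statistic t tests recompute the
case-control comparisons from them.  Raw images and per-subject values are
not part of the package.
"""

from __future__ import annotations

#: subjects screened / excluded / enrolled in the case arm
N_SCREENED_OI = 35
EXCLUDED_BY_REASON = {"poor_image_quality": 7, "lost_images": 8}

GROUP_N = {"OI": 20, "control": 40}
SEX_COUNTS = {"OI": {"male": 15, "female": 5},
              "control": {"male": 30, "female": 10}}
OI_TYPE_COUNTS = {"I": 15, "III": 2, "IV": 3}

#: demographics: variable -> group -> (mean, sd)
DEMOGRAPHICS = {
    "age": {"OI": (9.1, 3.3), "control": (9.7, 3.0)},
    "weight": {"OI": (38.4, 24.1), "control": (43.7, 18.8)},
    "height": {"OI": (131.7, 26.8), "control": (144.6, 19.0)},
    "bmi": {"OI": (19.8, 4.6), "control": (20.0, 4.9)},
}

#: muscle endpoints: (method, level, metric) -> group -> (mean, sd)
MEASUREMENTS = {
    ("fixed", "midT4", "area_cm2"): {"OI": (93.1, 33.4), "control": (108.9, 34.2)},
    ("fixed", "midT4", "density_hu"): {"OI": (41.2, 5.5), "control": (48.0, 4.7)},
    ("fixed", "midT10", "area_cm2"): {"OI": (41.7, 15.5), "control": (51.0, 18.9)},
    ("fixed", "midT10", "density_hu"): {"OI": (37.3, 6.8), "control": (45.9, 6.2)},
    ("gmm", "midT4", "area_cm2"): {"OI": (110.9, 18.4), "control": (127.2, 36.8)},
    ("gmm", "midT4", "density_hu"): {"OI": (44.6, 7.3), "control": (51.3, 4.3)},
    ("gmm", "midT10", "area_cm2"): {"OI": (72.6, 16.4), "control": (88.0, 23.8)},
    ("gmm", "midT10", "density_hu"): {"OI": (41.6, 10.4), "control": (50.3, 6.3)},
}

#: method agreement (fixed - GMM): variable -> (mean difference, LoA lower, LoA upper)
AGREEMENT = {
    "T4 muscle size (cm2)": (-18.05, -97.30, 61.19),
    "T4 muscle density (HU)": (-3.34, -10.84, 4.16),
    "T10 muscle size (cm2)": (-34.94, -90.51, 20.62),
    "T10 muscle density (HU)": (-4.34, -13.59, 4.90),
}
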