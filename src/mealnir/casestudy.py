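"""Reference values for the mealworm feeding-trial case study.

Fifteen rearing groups of Tenebrio molitor larvae: wheat bran (WB)
alone or blended with coconut flour (CF), flaxseed flour (FSF), grape
pomace (GP), hemp protein flour (HPF), rose hip hulls (RHH) or pea
protein flour (PPF); group names carry the dietary fat target, e.g.
CF15 = coconut flour + wheat bran at 15% total fat.

These constants drive the verification command, the synthetic-data
generator's group structure, and the in-package arithmetic checks
(class sums, diet-mixing inversion, RPD identities).
"""

from __future__ import annotations

GROUPS = (
    "CF5", "CF10", "CF15", "CF20",
    "FSF5", "FSF10", "FSF15", "FSF20",
    "GP4", "HPF5", "HPF8", "RHH4", "PPF5", "PPF6", "WB",
)

#: substrate inclusion (% of diet mass; remainder is wheat bran)
DIET_INCLUSION = {
    "CF5": 3.4, "CF10": 23.8, "CF15": 46.2, "CF20": 68.6,
    "FSF5": 1.1, "FSF10": 18.7, "FSF15": 36.4, "FSF20": 54.1,
    "GP4": 42.5, "HPF5": 14.5, "HPF8": 71.5, "RHH4": 36.4,
    "PPF5": 7.8, "PPF6": 38.6, "WB": 0.0,
}

#: diet nutrient composition, % fresh weight
DIET_NUTRIENTS = {
    "CF5":  {"moisture": 12.0, "protein": 14.9, "fat": 5.0,  "carbohydrate": 44.9, "fiber": 17.6, "ash": 5.6},
    "CF10": {"moisture": 11.2, "protein": 15.2, "fat": 10.0, "carbohydrate": 43.3, "fiber": 15.6, "ash": 4.8},
    "CF15": {"moisture": 10.4, "protein": 15.4, "fat": 15.0, "carbohydrate": 41.8, "fiber": 13.5, "ash": 3.9},
    "CF20": {"moisture": 9.6,  "protein": 15.7, "fat": 20.0, "carbohydrate": 40.2, "fiber": 11.5, "ash": 3.0},
    "FSF5": {"moisture": 12.0, "protein": 15.0, "fat": 5.0,  "carbohydrate": 44.8, "fiber": 17.6, "ash": 5.7},
    "FSF10": {"moisture": 11.2, "protein": 16.4, "fat": 10.0, "carbohydrate": 41.3, "fiber": 15.6, "ash": 5.5},
    "FSF15": {"moisture": 10.5, "protein": 17.8, "fat": 15.0, "carbohydrate": 37.7, "fiber": 13.7, "ash": 5.3},
    "FSF20": {"moisture": 9.8,  "protein": 19.2, "fat": 20.0, "carbohydrate": 34.2, "fiber": 11.7, "ash": 5.1},
    "GP4":  {"moisture": 11.0, "protein": 12.0, "fat": 4.4,  "carbohydrate": 51.0, "fiber": 16.7, "ash": 5.0},
    "HPF5": {"moisture": 11.6, "protein": 20.0, "fat": 5.3,  "carbohydrate": 39.6, "fiber": 18.0, "ash": 5.5},
    "HPF8": {"moisture": 9.9,  "protein": 40.0, "fat": 7.8,  "carbohydrate": 18.4, "fiber": 19.3, "ash": 4.6},
    "RHH4": {"moisture": 12.0, "protein": 10.8, "fat": 3.5,  "carbohydrate": 51.0, "fiber": 17.0, "ash": 5.7},
    "PPF5": {"moisture": 11.3, "protein": 20.0, "fat": 5.0,  "carbohydrate": 41.9, "fiber": 16.6, "ash": 5.3},
    "PPF6": {"moisture": 8.4,  "protein": 40.0, "fat": 6.0,  "carbohydrate": 29.5, "fiber": 12.5, "ash": 3.6},
    "WB":   {"moisture": 12.0, "protein": 14.9, "fat": 4.7,  "carbohydrate": 45.0, "fiber": 17.7, "ash": 5.7},
}

#: larval fatty-acid composition per group, relative % of total FA
#: (dry-matter basis); None = not detected
FA_PROFILES = {
    "Start": {"C12:0": None, "C14:0": 3.3, "C16:0": 23.0, "C16:1": 1.4,
              "C18:0": 4.7, "C18:1w9": 31.3, "C18:2w6": 34.8, "C18:3w3": 1.4},
    "CF5":  {"C12:0": 0.7, "C14:0": 4.8, "C16:0": 22.2, "C16:1": 1.6,
             "C18:0": 2.9, "C18:1w9": 39.8, "C18:2w6": 27.2, "C18:3w3": 0.9},
    "CF10": {"C12:0": 4.6, "C14:0": 12.2, "C16:0": 21.4, "C16:1": 2.4,
             "C18:0": 3.1, "C18:1w9": 36.1, "C18:2w6": 19.1, "C18:3w3": 1.0},
    "CF15": {"C12:0": 4.7, "C14:0": 12.9, "C16:0": 20.1, "C16:1": 1.5,
             "C18:0": 2.7, "C18:1w9": 41.2, "C18:2w6": 16.5, "C18:3w3": 0.5},
    "CF20": {"C12:0": 3.2, "C14:0": 11.4, "C16:0": 19.2, "C16:1": 1.7,
             "C18:0": 3.2, "C18:1w9": 44.8, "C18:2w6": 16.3, "C18:3w3": 0.2},
    "FSF5": {"C12:0": 0.6, "C14:0": 3.3, "C16:0": 19.3, "C16:1": 2.1,
             "C18:0": 3.5, "C18:1w9": 43.1, "C18:2w6": 25.9, "C18:3w3": 2.1},
    "FSF10": {"C12:0": 0.6, "C14:0": 4.4, "C16:0": 19.3, "C16:1": 1.9,
              "C18:0": 3.4, "C18:1w9": 40.8, "C18:2w6": 21.3, "C18:3w3": 8.4},
    "FSF15": {"C12:0": None, "C14:0": None, "C16:0": 22.2, "C16:1": 1.4,
              "C18:0": 4.2, "C18:1w9": 37.1, "C18:2w6": 22.1, "C18:3w3": 13.0},
    "FSF20": {"C12:0": 0.5, "C14:0": 4.2, "C16:0": 19.5, "C16:1": 1.8,
              "C18:0": 4.0, "C18:1w9": 40.3, "C18:2w6": 19.2, "C18:3w3": 10.5},
    "GP4":  {"C12:0": 0.7, "C14:0": 6.4, "C16:0": 27.1, "C16:1": 2.3,
             "C18:0": 2.9, "C18:1w9": 36.8, "C18:2w6": 22.7, "C18:3w3": 1.1},
    "HPF5": {"C12:0": 0.7, "C14:0": 5.0, "C16:0": 22.5, "C16:1": 2.2,
             "C18:0": 3.4, "C18:1w9": 34.7, "C18:2w6": 29.5, "C18:3w3": 2.0},
    "HPF8": {"C12:0": 0.9, "C14:0": 4.4, "C16:0": 19.2, "C16:1": 2.5,
             "C18:0": 2.9, "C18:1w9": 35.7, "C18:2w6": 30.8, "C18:3w3": 3.8},
    "RHH4": {"C12:0": 0.7, "C14:0": 6.1, "C16:0": 27.1, "C16:1": 2.0,
             "C18:0": 2.8, "C18:1w9": 34.4, "C18:2w6": 25.3, "C18:3w3": 1.4},
    "PPF5": {"C12:0": 1.0, "C14:0": 4.4, "C16:0": 23.1, "C16:1": 2.3,
             "C18:0": 3.0, "C18:1w9": 35.0, "C18:2w6": 29.8, "C18:3w3": 1.4},
    "PPF6": {"C12:0": None, "C14:0": 5.6, "C16:0": 21.4, "C16:1": 2.1,
             "C18:0": 6.7, "C18:1w9": 30.5, "C18:2w6": 32.1, "C18:3w3": 1.7},
    "WB":   {"C12:0": 0.8, "C14:0": 3.8, "C16:0": 21.7, "C16:1": 1.6,
             "C18:0": 3.1, "C18:1w9": 37.4, "C18:2w6": 30.3, "C18:3w3": 1.3},
}

#: published class sums per group (% of total FA): (SFA, MUFA, PUFA)
PRINTED_CLASS_SUMS = {
    "Start": (31.0, 32.8, 36.2),
    "CF5": (30.6, 41.4, 28.0),
    "CF10": (41.4, 38.6, 20.1),
    "CF15": (40.4, 42.7, 16.9),
    "CF20": (40.0, 46.5, 16.6),
    "FSF5": (26.8, 45.2, 28.0),
    "FSF10": (27.6, 42.7, 29.7),
    "FSF15": (26.3, 38.5, 35.1),
    "FSF20": (28.2, 42.1, 29.7),
    "GP4": (36.2, 39.1, 23.8),
    "HPF5": (31.6, 36.4, 31.5),
    "HPF8": (27.3, 38.2, 34.5),
    "RHH4": (36.9, 36.4, 26.7),
    "PPF5": (31.6, 36.9, 31.5),
    "PPF6": (33.6, 32.6, 33.8),
    "WB": (29.3, 39.1, 31.7),
}

#: printed sums known to disagree with their own printed components by
#: more than rounding (component sums in parentheses): CF20 SFA (37.0),
#: GP4 SFA (37.1), HPF5 MUFA (36.9), PPF5 MUFA (37.3), PPF5 PUFA (31.2)
KNOWN_SUM_DISCREPANCIES = (
    ("CF20", "sfa"),
    ("GP4", "sfa"),
    ("HPF5", "mufa"),
    ("PPF5", "mufa"),
    ("PPF5", "pufa"),
)

#: fat reference summaries (g/100 g FW): mean, min, max, SD
FAT_SUMMARY = {
    "calibration": {"mean": 12.0, "minimum": 7.4, "maximum": 16.2, "sd": 2.3},
    "validation": {"mean": 12.1, "minimum": 7.3, "maximum": 16.2, "sd": 2.3},
}

#: validation-set reference SDs per analyte (fatty acids % DW; fat g/100 g)
VALIDATION_SD = {
    "fat": 2.3,
    "C12:0": 1.4, "C14:0": 3.3, "C16:0": 2.7, "C16:1": 0.4, "C18:0": 1.0,
    "C18:1w9": 4.2, "C18:2w6": 5.6, "C18:3w3": 4.0,
    "SFA": 4.6, "MUFA": 4.2, "PUFA": 6.4,
}

#: published best-model statistics per analyte:
#: (pretreatment, n_lv, r2_c, rmsec, r2_p, rmsep, rpd, r2_f)
BEST_MODELS = {
    "fat":     ("mc", 6, 0.975, 0.355, 0.986, 0.276, 8.33, None),
    "C12:0":   ("none", 8, 0.915, 0.418, 0.917, 0.375, 3.73, 0.253),
    "C14:0":   ("msc", 8, 0.947, 0.773, 0.930, 0.803, 4.11, 0.331),
    "C16:0":   ("msc+detrend", 8, 0.812, 1.077, 0.877, 1.012, 2.66, 0.269),
    "C16:1":   ("detrend", 8, 0.337, 0.290, 0.345, 0.255, 1.57, 0.156),
    "C18:0":   ("d2", 8, 0.579, 0.638, 0.510, 0.509, 1.96, 0.071),
    "C18:1w9": ("msc", 8, 0.922, 1.104, 0.949, 0.756, 5.55, 0.527),
    "C18:2w6": ("msc", 8, 0.925, 1.602, 0.931, 1.411, 3.98, 0.568),
    "C18:3w3": ("msc", 8, 0.964, 0.713, 0.945, 0.817, 4.90, 0.019),
    "SFA":     ("msc", 8, 0.948, 1.088, 0.942, 1.081, 4.26, 0.091),
    "MUFA":    ("msc", 8, 0.886, 1.371, 0.903, 1.050, 4.00, 0.511),
    "PUFA":    ("msc", 8, 0.943, 1.466, 0.878, 2.115, 3.03, 0.282),
}

#: fat-content screening statistics per pretreatment:
#: (n_lv, r2_c, rmsec, r2_p, rmsep, rpd)
FAT_MODEL_SCREEN = {
    "none": (6, 0.955, 0.482, 0.967, 0.431, 5.34),
    "msc":  (5, 0.962, 0.443, 0.969, 0.412, 5.58),
    "mc":   (6, 0.975, 0.355, 0.986, 0.276, 8.33),
    "d1":   (4, 0.949, 0.512, 0.954, 0.502, 4.58),
    "d2":   (5, 0.958, 0.461, 0.961, 0.467, 4.93),
}
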