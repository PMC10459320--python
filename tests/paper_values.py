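"""Frozen published reference values used as test expectations.

TOLERANCE_TABLE: safe-Ht bands per population block; one entry per block:
(group, postnatal_day, ht_cal, {error_level: (ht_low, ht_high)}), bounds at
2 decimals.  The entire-population block uses the fixed calibration Ht 50%.

CUTOFF_BOUNDARIES: the published 33-marker cut-off panel with the printed
10%-difference boundary concentration (3 decimals): (marker, cutoff,
direction, boundary).
"""

TOLERANCE_TABLE = [
    ("entire", None, 50, {1: (48.60, 51.37), 3: (45.71, 54.04), 5: (42.71, 56.60)}),
    ("term", 0, 53, {1: (51.63, 54.34), 3: (48.81, 56.95), 5: (45.86, 59.46)}),
    ("preterm", 0, 50, {1: (48.60, 51.37), 3: (45.71, 54.04), 5: (42.71, 56.60)}),
    ("term", 1, 51, {1: (49.61, 52.36), 3: (46.75, 55.01), 5: (43.76, 57.55)}),
    ("preterm", 1, 49, {1: (47.59, 50.38), 3: (44.68, 53.07), 5: (41.65, 55.65)}),
    ("term", 2, 50, {1: (48.60, 51.37), 3: (45.71, 54.04), 5: (42.71, 56.60)}),
    ("preterm", 2, 47, {1: (45.57, 48.40), 3: (42.62, 51.12), 5: (39.55, 53.74)}),
    ("term", 3, 49, {1: (47.59, 50.38), 3: (44.68, 53.07), 5: (41.65, 55.65)}),
    ("preterm", 3, 45, {1: (43.55, 46.42), 3: (40.56, 49.18), 5: (37.44, 51.84)}),
    ("term", 7, 45, {1: (43.55, 46.42), 3: (40.56, 49.18), 5: (37.44, 51.84)}),
    ("preterm", 7, 44, {1: (42.54, 45.43), 3: (39.53, 48.21), 5: (36.39, 50.88)}),
    ("term", 14, 42, {1: (40.52, 43.45), 3: (37.47, 46.27), 5: (34.29, 48.98)}),
    ("preterm", 14, 38, {1: (36.48, 39.49), 3: (33.34, 42.39), 5: (30.08, 45.17)}),
    ("term", 28, 38, {1: (36.48, 39.49), 3: (33.34, 42.39), 5: (30.08, 45.17)}),
    ("preterm", 28, 31, {1: (29.41, 32.56), 3: (26.13, 35.59), 5: (22.71, 38.50)}),
]

CUTOFF_BOUNDARIES = [
    ("Val", 290.000, "up", 261.000),
    ("Leu", 245.000, "up", 220.500),
    ("Met", 63.000, "up", 56.700),
    ("Phe", 153.000, "up", 137.700),
    ("Tyr", 190.000, "up", 171.000),
    ("Glu", 560.000, "up", 504.000),
    ("Orn", 250.000, "up", 225.000),
    ("Cit", 65.000, "up", 58.500),
    ("Arg", 100.000, "up", 90.000),
    ("Ala", 900.000, "up", 810.000),
    ("Gly", 1000.000, "up", 900.000),
    ("C0", 6.250, "down", 6.875),
    ("C3", 7.000, "up", 6.300),
    ("C4", 1.690, "up", 1.521),
    ("C4-OH", 0.550, "up", 0.495),
    ("C5", 1.000, "up", 0.900),
    ("C5:1", 0.450, "up", 0.405),
    ("C5-OH", 1.040, "up", 0.936),
    ("C6DC", 0.270, "up", 0.243),
    ("C6", 0.470, "up", 0.423),
    ("C8", 0.350, "up", 0.315),
    ("C10:2", 0.500, "up", 0.450),
    ("C10:1", 0.300, "up", 0.270),
    ("C10", 0.420, "up", 0.378),
    ("C3DC", 0.250, "up", 0.225),
    ("C5DC", 0.300, "up", 0.270),
    ("C14:1", 0.640, "up", 0.576),
    ("C14", 0.810, "up", 0.729),
    ("C16:1", 0.340, "up", 0.306),
    ("C16", 9.280, "up", 8.352),
    ("C18:1", 3.000, "up", 2.700),
    ("C16-OH", 0.230, "up", 0.207),
    ("C18:1-OH", 0.750, "up", 0.675),
]

# Mean reference hematocrit (%) per gestational group x post-natal day, SD 6.
REFERENCE_MEANS = {
    "term": {0: 53, 1: 51, 2: 50, 3: 49, 7: 45, 14: 42, 28: 38},
    "preterm": {0: 50, 1: 49, 2: 47, 3: 45, 7: 44, 14: 38, 28: 31},
}
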