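"""Published reference values from the Pantanal mesocarnivore study design.

These are the printed per-individual home-range statistics and camera-trap
totals for a radio-tracked assemblage of ocelots, crab-eating foxes and
brown-nosed coatis at a Pantanal ranch site, used as worked-example inputs
(e.g. for :func:`nichekit.summarize_home_ranges`) and as fixed numeric
anchors in the test suite.  Only numbers printed in the original report are
stored here; no field data are included.
"""

from __future__ import annotations

import pandas as pd

SITE_LATITUDE = -18.983   # ~ 18 deg 59' S
SITE_LONGITUDE = -56.65   # ~ 56 deg 39' W
SITE_UTC_OFFSET = -4.0

#: Per-individual home-range table: species, id, sex, number of radio
#: locations, 95% fixed-kernel UD area (km^2), percent of locations by
#: day/night, and days of monitoring.
HOME_RANGE_TABLE = pd.DataFrame(
    [
        ("ocelot", "LP1", "F", 77, 7.0, 53.2, 46.8, 618),
        ("ocelot", "LP2", "F", 52, 4.5, 50.0, 50.0, 613),
        ("ocelot", "LP3", "F", 42, 8.0, 73.8, 26.2, 348),
        ("ocelot", "LP4", "F", 21, 8.8, 52.4, 47.6, 85),
        ("ocelot", "LP5", "M", 59, 16.1, 50.8, 49.2, 502),
        ("ocelot", "LP6", "M", 34, 3.8, 61.8, 38.2, 169),
        ("crab-eating fox", "CT1", "F", 53, 2.3, 37.7, 62.3, 350),
        ("crab-eating fox", "CT2", "M", 86, 1.2, 62.1, 37.9, 472),
        ("crab-eating fox", "CT3", "M", 83, 1.4, 48.6, 51.4, 774),
        ("crab-eating fox", "CT4", "F", 93, 2.2, 50.4, 49.6, 427),
        ("crab-eating fox", "CT5", "F", 79, 1.7, 62.7, 37.3, 473),
        ("crab-eating fox", "CT6", "F", 65, 1.0, 58.1, 41.9, 471),
        ("crab-eating fox", "CT7", "M", 45, 0.9, 56.8, 43.2, 298),
        ("brown-nosed coati", "NN1", "F", 66, 3.4, 59.1, 40.9, 823),
        ("brown-nosed coati", "NN2", "F", 57, 3.6, 66.7, 33.3, 287),
        ("brown-nosed coati", "NN3", "F", 51, 1.5, 82.4, 17.6, 486),
        ("brown-nosed coati", "NN4", "F", 39, 1.5, 61.5, 38.5, 171),
        ("brown-nosed coati", "NN5", "M", 33, 1.2, 51.5, 48.5, 354),
        ("brown-nosed coati", "NN6", "M", 55, 0.6, 76.4, 23.6, 472),
        ("brown-nosed coati", "NN7", "M", 19, 1.4, 47.4, 52.6, 155),
    ],
    columns=["species", "animal_id", "sex", "n_locations", "ud_km2",
             "pct_day", "pct_night", "days_monitored"],
)

#: Camera-trap survey totals: effort and per-species record counts.
CAMERA_TRAP_DAYS = 2238
CAMERA_TOTAL_RECORDS = 1773
CAMERA_COUNTS = {
    "crab-eating fox": 1176,
    "brown-nosed coati": 419,
    "crab-eating raccoon": 77,
    "ocelot": 68,
}

#: Published Wilks' lambda triples (lambda, N individuals, printed chi2) for
#: the species-by-design compositional tests; df = 4 throughout.
WILKS_TRIPLES = [
    ("ocelot", "II", 0.340, 6, 6.473),
    ("ocelot", "III", 0.111, 6, 13.206),
    ("crab-eating fox", "II", 0.092, 7, 16.635),
    ("crab-eating fox", "III", 0.650, 7, 3.021),
    ("brown-nosed coati", "II", 0.698, 7, 2.515),
    ("brown-nosed coati", "III", 0.192, 7, 11.539),
]
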