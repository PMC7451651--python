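"""Reference inputs for the Pan'an Lake study area (Jiawang District, Xuzhou).

The Pan'an Lake wetland is China's first wetland park reclaimed from a coal
mining subsidence lake. These constants are the published study-area inputs
— the before/after (2008/2017) landscape structure from remote-sensing
interpretation, and the per-class ESV and ecological-storage summaries —
used to build the bundled fixture and to validate the valuation pipeline
against the published tables. Areas are hm^2; ESV values are 万元.
"""

from __future__ import annotations

#: code -> class name legend shared by both epochs.
LEGEND: dict[int, str] = {
    1: "cultivated",
    2: "woodland",
    3: "grassland",
    4: "transportation",
    5: "natural_water",
    6: "built_up",
    7: "subsided_water",
}

#: Landscape structure before reclamation (2008), hm^2.
AREAS_2008: dict[str, float] = {
    "cultivated": 2918.97,
    "woodland": 33.62,
    "grassland": 128.75,
    "transportation": 209.69,
    "natural_water": 336.59,
    "built_up": 1098.91,
    "subsided_water": 582.89,
}

#: Landscape structure after reclamation (2017), hm^2.
AREAS_2017: dict[str, float] = {
    "cultivated": 2084.89,
    "woodland": 449.84,
    "grassland": 498.67,
    "transportation": 223.85,
    "natural_water": 1071.63,
    "built_up": 980.54,
    "subsided_water": 0.0,
}

TOTAL_AREA_HM2 = 5309.42

#: Published per-class ESV (万元) before/after reclamation. The 2017
#: transportation and built-up entries are not consistent with the 2017
#: areas above times the coefficient table (they imply areas 238.85 and
#: 965.52 hm^2); they are carried verbatim for validation against the
#: published totals and change rates.
ESV_2008: dict[str, float] = {
    "cultivated": 1784.75,
    "woodland": 65.0,
    "grassland": 82.49,
    "transportation": -112.65,
    "natural_water": 1369.12,
    "built_up": -193.46,
    "subsided_water": 590.81,
}

ESV_2017: dict[str, float] = {
    "cultivated": 1274.77,
    "woodland": 869.73,
    "grassland": 319.47,
    "transportation": -128.31,
    "natural_water": 4359.02,
    "built_up": -169.98,
    "subsided_water": 0.0,
}

ESV_TOTAL_2008 = 3586.06
ESV_TOTAL_2017 = 6524.69

#: The 2017 classes whose published ESV equals area x coefficient to 2 dp.
CONSISTENT_2017_CLASSES = (
    "cultivated", "woodland", "grassland", "natural_water", "subsided_water",
)

#: Ecological storage states (万元/hm^2) and their conversion over 9 years.
ESS_2008 = 0.6754
ESS_2017 = 1.2289
ESS_CONVERSION_QUANTITY = 0.5535
ESS_CONVERSION_PERCENT = 6.15
STUDY_YEARS = 9
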