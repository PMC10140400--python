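"""Reference cohort profile: a large airport-company workforce survey.

The default synthetic cohort emulates a published cross-sectional survey of
airport employees (N = 5,794 valid responses out of 6,689 returned) in which
728 respondents screened as high occupational-burnout risk on the MBI-GS.
The per-level counts below are the baseline-characteristics ("table one")
marginals of that cohort, split by burnout-risk group, and drive both the
default simulation schema and the worked examples in the test suite.

Counts are stored as ``(low, high)`` pairs per level.  Where the published
overall column is internally inconsistent with the group counts, the group
counts (which are consistent) are authoritative; overall marginals are
derived as low + high.
"""

from __future__ import annotations

# Cohort totals
N_RETURNED = 6689
N_VALID = 5794
N_LOW = 5066
N_HIGH = 728

# (category, variable, kind, {level: (low_count, high_count)})
# kind is one of: "ordinal", "nominal", "binary"
CATEGORICAL_COUNTS: list[tuple[str, str, str, dict[str, tuple[int, int]]]] = [
    ("demographic", "Sex", "binary",
     {"Female": (1882, 293), "Male": (3184, 435)}),
    ("demographic", "Marital status", "nominal",
     {"Married": (2987, 384), "Unmarried": (1946, 317),
      "Widowed": (15, 3), "Divorced": (118, 24)}),
    ("demographic", "Education background", "ordinal",
     {"High school": (1127, 126), "College": (2359, 369),
      "University": (1440, 221), "Graduate": (140, 12)}),
    ("work_related", "Type of position", "nominal",
     {"Management": (352, 42), "Profession": (1039, 153),
      "Aviation Technology": (1588, 275), "General Technology": (842, 105),
      "Assistant": (1245, 153)}),
    ("work_related", "Professional grade", "ordinal",
     {"6-8": (1353, 166), "9-10": (1858, 308), "11-13": (1084, 150),
      "14-15": (328, 42), "16-18": (300, 41), "19 or above": (124, 20),
      "others": (19, 1)}),
    ("health", "Self-rated health status", "ordinal",
     {"Healthy": (1093, 109), "Relatively healthy": (2107, 201),
      "Sub-health": (1605, 325), "Unhealthy": (261, 93)}),
    ("health", "Hospital admission in the last 3 years", "ordinal",
     {"Two or more times": (144, 38), "Once": (577, 77),
      "Never": (4345, 613)}),
    ("health", "Arthritis", "binary",
     {"Yes": (936, 189), "No": (4130, 539)}),
    ("health", "High blood pressure", "binary",
     {"Yes": (389, 69), "No": (4677, 659)}),
    ("health", "Cardiovascular diseases", "binary",
     {"Yes": (66, 25), "No": (5000, 703)}),
    ("health", "High blood lipid", "binary",
     {"Yes": (412, 94), "No": (4654, 634)}),
    ("health", "Breast diseases", "binary",
     {"Yes": (226, 57), "No": (4840, 671)}),
    ("health", "Overweight", "binary",
     {"Yes": (858, 143), "No": (4208, 585)}),
    ("health", "Other chronic diseases", "binary",
     {"Yes": (651, 153), "No": (4415, 575)}),
    ("lifestyle", "Breakfast frequency", "ordinal",
     {"Almost everyday": (2868, 322), "3 days or more per week": (1821, 302),
      "Less than 1 day per week": (377, 104)}),
    ("lifestyle", "Smoked food consumption", "ordinal",
     {"Often": (360, 71), "Sometimes": (3443, 482),
      "Almost never": (1263, 175)}),
    ("lifestyle", "Dairy consumption", "nominal",
     {"< 200 ML/day": (2261, 329), "200-300 ML/day": (976, 96),
      "> 400 ML/day": (158, 20), "Almost never": (1671, 283)}),
    ("lifestyle", "Salt-limiting tool usage", "ordinal",
     {"Almost never": (3329, 524), "Sometimes": (885, 100),
      "Often": (370, 41), "Always": (482, 63)}),
    ("lifestyle", "Change of taste", "nominal",
     {"Salty": (539, 99), "Light": (1273, 188), "No change": (3254, 441)}),
    ("lifestyle", "Oil-limiting tool usage", "ordinal",
     {"Almost never": (3637, 572), "Sometimes": (726, 77),
      "Often": (332, 36), "Always": (371, 43)}),
    ("lifestyle", "Change of oil consumption", "nominal",
     {"More": (395, 74), "Less": (1189, 149), "No change": (3482, 505)}),
    ("lifestyle", "Vegetable consumption", "nominal",
     {"Almost never": (379, 63), "1-3 times/week": (1094, 172),
      "4-6 times/week": (977, 111), "1 time/day": (858, 103),
      "2 times/day": (779, 97), "3 times/day": (132, 18),
      "Do not remember": (847, 164)}),
    ("lifestyle", "Pedometer usage", "ordinal",
     {"Often": (1435, 180), "Sometimes": (1333, 159), "Never": (2298, 389)}),
    ("lifestyle", "Weight status", "nominal",
     {"Underweight": (663, 115), "Normal": (1939, 253),
      "Overweight": (2061, 287), "Do not know": (403, 73)}),
    ("lifestyle", "Smoking", "ordinal",
     {"Everyday": (973, 155), "Sometimes": (682, 78), "Never": (3411, 495)}),
    ("lifestyle", "Consumed various types of food", "binary",
     {"Yes": (3629, 466), "No": (1437, 262)}),
    ("lifestyle", "Fresh fruit and vegetable consumption", "binary",
     {"Enough": (2701, 326), "Not enough": (2365, 402)}),
    ("lifestyle", "Oily food consumption", "binary",
     {"Often": (1174, 198), "Not often": (3892, 530)}),
    ("lifestyle", "Physical exercise participation", "binary",
     {"Often": (2400, 257), "Not often": (2666, 471)}),
    ("lifestyle", "Limit salt consumption", "binary",
     {"Yes": (3239, 394), "No": (1827, 334)}),
    ("lifestyle", "Limit oil consumption", "binary",
     {"Yes": (2543, 312), "No": (2523, 416)}),
    ("lifestyle", "Keep weight", "binary",
     {"Yes": (2702, 307), "No": (2364, 421)}),
]

# Numeric variables: (category, name, range, overall median, IQR,
#                     low median, low IQR, high median, high IQR)
NUMERIC_SUMMARIES: list[tuple] = [
    ("demographic", "Age", (16.0, 65.0),
     33.0, (25.0, 41.0), 33.0, (25.0, 41.0), 31.0, (25.0, 39.0)),
    ("lifestyle", "Walk time", (0.0, 1200.0),
     80.0, (60.0, 180.0), 76.5, (60.0, 180.0), 80.0, (60.0, 264.0)),
]
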