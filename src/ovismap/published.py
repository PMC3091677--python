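"""Published summary statistics of the first-generation bighorn sheep
integrated microsatellite linkage map, kept here as reference inputs.

These numbers are printed summaries (per-linkage-group map lengths, shared
interval direction counts against other maps, headline totals) of the
published integrated map for *Ovis canadensis* built from the National
Bison Range and Ram Mountain pedigrees.  They are inputs for arithmetic
cross-checks and worked examples — none of the package's estimation code
depends on them.

Row format of :data:`INTEGRATED_MAP_GROUPS`:
``(group, n_markers, n_intervals, sex_averaged_cM, female_cM, male_cM)``.
The X female/male entries are sex-limited and are included as printed.
"""

from __future__ import annotations

INTEGRATED_MAP_GROUPS: list[tuple[str, int, int, float, float, float]] = [
    ("1", 22, 21, 302.8, 326.3, 284.9),
    ("2", 18, 17, 274.3, 290.9, 264.0),
    ("3", 16, 15, 272.7, 303.5, 250.1),
    ("4", 10, 8, 142.7, 167.6, 124.0),
    ("5", 10, 8, 132.8, 125.2, 148.1),
    ("6", 13, 11, 138.9, 148.3, 135.4),
    ("7", 9, 8, 125.3, 136.8, 116.8),
    ("8", 9, 8, 127.9, 155.6, 122.9),
    ("9", 12, 10, 115.5, 122.5, 109.9),
    ("10", 10, 8, 64.2, 65.0, 64.0),
    ("11", 6, 5, 108.2, 118.3, 99.2),
    ("12", 9, 8, 102.9, 107.3, 99.5),
    ("13", 9, 8, 120.6, 122.5, 119.7),
    ("14", 9, 7, 82.5, 92.2, 75.3),
    ("15", 11, 10, 112.8, 110.5, 118.8),
    ("16", 5, 4, 67.6, 77.4, 62.3),
    ("17", 9, 7, 97.3, 100.5, 97.3),
    ("18", 10, 9, 96.9, 94.4, 97.4),
    ("19", 6, 5, 75.5, 75.5, 74.8),
    ("20", 6, 5, 71.5, 77.9, 66.3),
    ("21", 3, 2, 16.3, 16.6, 16.0),
    ("22", 5, 4, 51.9, 60.9, 45.8),
    ("23", 8, 7, 71.9, 82.0, 63.9),
    ("24", 3, 2, 44.0, 41.3, 47.9),
    ("25", 4, 3, 83.3, 89.0, 80.8),
    ("26", 6, 5, 51.3, 58.0, 46.0),
    ("X", 9, 8, 99.2, 170.6, 1.3),
]

#: printed Total row of the integrated map table
TOTAL_MARKERS = 247
TOTAL_INTERVALS = 213
TOTAL_SEX_AVERAGED_CM = 3050.8
TOTAL_FEMALE_CM = 3336.6
TOTAL_MALE_CM = 2832.4

#: headline autosomal sex-specific lengths (printed with the 1.12 ratio)
AUTOSOMAL_FEMALE_CM = 3166.1
AUTOSOMAL_MALE_CM = 2832.2

#: unique mapped positions (markers minus perfectly linked duplicates)
N_UNIQUE_POSITIONS = 240
N_LINKAGE_GROUPS = 27

#: printed shared-interval direction counts for the published sign tests:
#: (greater in first map, greater in second map)
SIGN_COUNTS_SPECIES = (105, 98)        # domestic sheep vs bighorn, sex-avg
SIGN_COUNTS_RM_FEMALE_MALE = (92, 72)  # Ram Mountain female vs male
SIGN_COUNTS_INTEGRATED_FEMALE_MALE = (119, 87)  # integrated female vs male

#: printed genome-coverage estimate against the reference map
COVERAGE_FRACTION = 0.84
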