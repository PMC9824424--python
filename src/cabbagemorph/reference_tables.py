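"""Published per-plant reference measurements for field-grown storage cabbage.

Ten hand-harvested plants per growth stage (BBCH 41, 45 and 48). For each
plant the tables hold the tape/scan-measured value, the value computed by this
measurement method on ground-truth segmentation masks ("calculated"), and the
value computed on network-predicted masks ("detected"). Head volumes are in
m³, leaf areas (visible leaves only) in m², leaf counts are integers.

These columns are the package's regression fixture: summary rows (mean,
population SD as a percent of the mean, mean accuracy against the measured
column) are always recomputed from the per-plant values, never stored.
"""

from __future__ import annotations

import pandas as pd

# BBCH 48, head volume (m³)
VOLUME_BBCH48 = pd.DataFrame(
    {
        "measured": [0.0018, 0.0034, 0.0028, 0.0031, 0.0032, 0.0029, 0.0022, 0.0034, 0.0036, 0.0022],
        "calculated": [0.0021, 0.0037, 0.0031, 0.0029, 0.0029, 0.0031, 0.0017, 0.0027, 0.0031, 0.0018],
        "detected": [0.0021, 0.0038, 0.0034, 0.0033, 0.0029, 0.0023, 0.0015, 0.0016, 0.0025, 0.0016],
    },
    index=pd.RangeIndex(1, 11, name="plant"),
)

# BBCH 45, head volume (m³)
VOLUME_BBCH45 = pd.DataFrame(
    {
        "measured": [0.00085, 0.00089, 0.00055, 0.00060, 0.00125, 0.00100, 0.00108, 0.00050, 0.00125, 0.00125],
        "calculated": [0.00089, 0.00089, 0.00058, 0.00081, 0.00104, 0.00077, 0.00110, 0.00048, 0.00061, 0.00112],
        "detected": [0.00091, 0.00087, 0.00051, 0.00069, 0.00129, 0.00065, 0.00104, 0.00014, 0.00054, 0.00114],
    },
    index=pd.RangeIndex(1, 11, name="plant"),
)

# BBCH 48, leaf area of visible leaves (m²) and leaf counts
LEAF_AREA_BBCH48 = pd.DataFrame(
    {
        "leaves_visible": [13, 15, 14, 16, 11, 15, 13, 15, 12, 15],
        "measured": [0.57, 0.71, 0.67, 0.71, 0.60, 0.85, 0.62, 0.82, 0.61, 0.67],
        "calculated": [0.58, 0.73, 0.68, 0.89, 0.58, 0.65, 0.62, 0.74, 0.55, 0.59],
        "leaves_detected": [12, 13, 14, 16, 11, 13, 13, 13, 12, 11],
        "detected": [0.51, 0.66, 0.68, 0.90, 0.59, 0.56, 0.63, 0.62, 0.54, 0.50],
    },
    index=pd.RangeIndex(1, 11, name="plant"),
)

# BBCH 45
LEAF_AREA_BBCH45 = pd.DataFrame(
    {
        "leaves_visible": [19, 18, 18, 17, 19, 22, 21, 17, 22, 21],
        "measured": [0.70, 0.69, 0.65, 0.59, 0.79, 0.80, 0.88, 0.42, 0.91, 0.91],
        "calculated": [0.65, 0.61, 0.72, 0.68, 0.75, 0.80, 0.93, 0.49, 0.81, 0.80],
        "leaves_detected": [16, 17, 16, 14, 16, 17, 19, 13, 13, 21],
        "detected": [0.54, 0.56, 0.70, 0.55, 0.72, 0.60, 0.82, 0.39, 0.48, 0.78],
    },
    index=pd.RangeIndex(1, 11, name="plant"),
)

# BBCH 41 (no head yet at this stage)
LEAF_AREA_BBCH41 = pd.DataFrame(
    {
        "leaves_visible": [18, 18, 19, 17, 15, 17, 18, 19, 16, 14],
        "measured": [0.18, 0.18, 0.21, 0.22, 0.23, 0.19, 0.23, 0.22, 0.15, 0.19],
        "calculated": [0.16, 0.18, 0.22, 0.24, 0.19, 0.17, 0.20, 0.25, 0.15, 0.18],
        "leaves_detected": [13, 15, 17, 15, 12, 14, 13, 15, 14, 14],
        "detected": [0.09, 0.16, 0.20, 0.22, 0.22, 0.15, 0.19, 0.22, 0.16, 0.19],
    },
    index=pd.RangeIndex(1, 11, name="plant"),
)

TABLES: dict[str, pd.DataFrame] = {
    "volume_bbch48": VOLUME_BBCH48,
    "volume_bbch45": VOLUME_BBCH45,
    "leaf_area_bbch48": LEAF_AREA_BBCH48,
    "leaf_area_bbch45": LEAF_AREA_BBCH45,
    "leaf_area_bbch41": LEAF_AREA_BBCH41,
}
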