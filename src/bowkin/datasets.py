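"""Published summary tables of the haptic violin-training study.

The study's raw recordings are not publicly deposited, but its report
prints per-participant characteristics and group-level metric summaries.
These printed tables are inputs the package can recompute descriptive
statistics from (and that the synthetic generator is sized against).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["participant_characteristics", "group_stage_metric_summary"]

# participant number, age (years), weight (kg), height (cm), MSI score
_AVE_ROWS = [
    (1, 38, 82, 185, 4.4),
    (2, 63, 80, 192, 5.4),
    (3, 39, 80, 197, 4.9),
    (4, 35, 64, 184, 3.1),
    (5, 28, 67, 169, 4.4),
    (6, 40, 85, 185, 4.3),
    (7, 42, 71, 181, 3.3),
    (8, 40, 75, 183, 4.1),
    (9, 22, 73, 175, 3.3),
    (10, 50, 95, 178, 4.8),
    (11, 23, 75, 183, 2.9),
    (12, 27, 85, 187, 3.8),
]
_AV_ROWS = [
    (13, 28, 70, 175, 4.0),
    (14, 21, 70, 185, 4.2),
    (15, 36, 72, 182, 3.3),
    (16, 40, 70, 180, 4.6),
    (17, 38, 95, 186, 2.9),
    (18, 29, 81, 185, 4.6),
    (19, 25, 61, 176, 3.9),
    (20, 30, 75, 178, 3.3),
    (21, 31, 85, 194, 3.9),
    (22, 53, 75, 184, 4.3),
    (23, 28, 84, 198, 5.1),
    (24, 45, 79, 185, 4.2),
]


def participant_characteristics() -> pd.DataFrame:
    """Characteristics of the 24 participants (12 haptic AVE, 12 control
    AV): age in years, weight in kg, height in cm, and the Goldsmiths
    Musical Sophistication Index score."""
    cols = ["participant", "age", "weight", "height", "msi"]
    ave = pd.DataFrame(_AVE_ROWS, columns=cols).assign(group="AVE")
    av = pd.DataFrame(_AV_ROWS, columns=cols).assign(group="AV")
    return pd.concat([ave, av], ignore_index=True)


# metric, group, stage, mean, sd — the group-level mean +- SD summaries
# of the 13 analysed metrics (teacher values under group "teacher",
# stage "all"); units as in the analysis: deg for m2/m3/m10-m12,
# s for m13, a.u. otherwise
_SUMMARY_ROWS = [
    ("m2", "AV", "S1", 36.7, 8.6), ("m2", "AV", "S3", 45.8, 8.6),
    ("m2", "AVE", "S1", 36.0, 11.0), ("m2", "AVE", "S3", 46.9, 7.8),
    ("m2", "teacher", "all", 45.4, 2.5),
    ("m3", "AV", "S1", 62.0, 16.0), ("m3", "AV", "S3", 61.0, 18.0),
    ("m3", "AVE", "S1", 55.0, 20.0), ("m3", "AVE", "S3", 52.0, 25.0),
    ("m3", "teacher", "all", 64.1, 5.0),
    ("m4", "AV", "S1", 1.29, 0.59), ("m4", "AV", "S3", 2.7, 2.1),
    ("m4", "AVE", "S1", 1.42, 0.81), ("m4", "AVE", "S3", 2.7, 1.8),
    ("m4", "teacher", "all", 2.11, 0.37),
    ("m6", "AV", "S1", 13.4, 3.5), ("m6", "AV", "S3", 22.0, 13.0),
    ("m6", "AVE", "S1", 14.8, 5.9), ("m6", "AVE", "S3", 23.0, 12.0),
    ("m6", "teacher", "all", 16.5, 2.5),
    ("m8", "AV", "S1", 12.05, 4.37), ("m8", "AV", "S3", 9.7, 2.6),
    ("m8", "AVE", "S1", 12.8, 7.9), ("m8", "AVE", "S3", 8.9, 1.3),
    ("m8", "teacher", "all", 7.86, 0.26),
    ("m10", "AV", "S1", 2.2, 1.1), ("m10", "AV", "S3", 2.3, 1.2),
    ("m10", "AVE", "S1", 2.1, 1.1), ("m10", "AVE", "S3", 1.86, 0.65),
    ("m10", "teacher", "all", 1.25, 0.23),
    ("m11", "AV", "S1", 3.6, 1.9), ("m11", "AV", "S3", 3.7, 1.8),
    ("m11", "AVE", "S1", 2.6, 1.0), ("m11", "AVE", "S3", 2.3, 1.1),
    ("m11", "teacher", "all", 1.49, 0.38),
    ("m12", "AV", "S1", 34.0, 34.0), ("m12", "AV", "S3", 29.0, 24.0),
    ("m12", "AVE", "S1", 20.0, 18.0), ("m12", "AVE", "S3", 17.0, 16.0),
    ("m12", "teacher", "all", 6.2, 1.8),
    ("m13", "AV", "S1", 19.0, 20.0), ("m13", "AV", "S3", 0.0, 27.0),
    ("m13", "AVE", "S1", 6.0, 7.0), ("m13", "AVE", "S3", 13.0, 14.0),
    ("m14", "AV", "S1", 66.0, 24.0), ("m14", "AV", "S3", 49.0, 23.0),
    ("m14", "AVE", "S1", 78.0, 38.0), ("m14", "AVE", "S3", 42.0, 17.0),
    ("m15", "AV", "S1", -1.90, 0.13), ("m15", "AV", "S3", -1.795, 0.086),
    ("m15", "AVE", "S1", -1.89, 0.12), ("m15", "AVE", "S3", -1.791, 0.065),
    ("m15", "teacher", "all", -1.758, 0.019),
    ("m16", "AV", "S1", 0.896, 0.062), ("m16", "AV", "S3", 0.923, 0.075),
    ("m16", "AVE", "S1", 0.82, 0.20), ("m16", "AVE", "S3", 0.935, 0.048),
    ("m17", "AV", "S1", -0.07, 0.15), ("m17", "AV", "S3", 0.04, 0.24),
    ("m17", "AVE", "S1", -0.16, 0.77), ("m17", "AVE", "S3", -0.04, 0.17),
]


def group_stage_metric_summary() -> pd.DataFrame:
    """Group-level mean +- SD of the 13 analysed metrics at baseline
    (S1) and recall (S3), plus the teacher's values where applicable."""
    return pd.DataFrame(_SUMMARY_ROWS, columns=["metric", "group", "stage", "mean", "sd"])
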