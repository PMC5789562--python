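"""Published benchmark beat-detection counts used to exercise the metric
arithmetic.

These are per-record detection counts (total reference beats, TP, FP, FN)
reported for a two-level-CNN detector of this architecture on the 46 MLII
records of the MIT-BIH Arrhythmia database and, pooled, on the INCART
database.  The package uses them as fixed inputs: recomputing Sen, PPR,
DER and Acc from these integers and comparing against the printed
percentages checks the metric formulas and their 2-decimal rounding
convention end to end.  No waveform data is involved.

Each MIT-BIH row: (record, total, tp, fp, fn, sen, ppr, der, acc), where
the last four columns are the published 2-decimal percentages.
"""

from __future__ import annotations

__all__ = ["MITDB_RECORD_ROWS", "MITDB_OVERALL_ROW", "INCART_ROW"]

MITDB_RECORD_ROWS = [
    ("100", 2273, 2273, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("101", 1865, 1865, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("103", 2084, 2084, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("105", 2572, 2560, 0, 12, 99.53, 100.00, 0.47, 99.53),
    ("106", 2027, 2010, 8, 17, 99.16, 99.60, 1.23, 98.77),
    ("107", 2137, 2137, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("108", 1763, 1763, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("109", 2532, 2523, 7, 9, 99.64, 99.72, 0.63, 99.37),
    ("111", 2124, 2124, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("112", 2539, 2539, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("113", 1795, 1795, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("114", 1879, 1872, 5, 7, 99.63, 99.73, 0.64, 99.36),
    ("115", 1953, 1953, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("116", 2412, 2398, 6, 14, 99.42, 99.75, 0.83, 99.17),
    ("117", 1535, 1535, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("118", 2278, 2277, 1, 1, 99.96, 99.96, 0.09, 99.91),
    ("119", 1987, 1976, 8, 11, 99.45, 99.60, 0.96, 99.05),
    ("121", 1863, 1863, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("122", 2476, 2476, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("123", 1518, 1517, 2, 1, 99.93, 99.87, 0.20, 99.80),
    ("124", 1619, 1617, 5, 2, 99.88, 99.69, 0.43, 99.57),
    ("200", 2601, 2596, 1, 5, 99.81, 99.96, 0.23, 99.77),
    ("201", 1963, 1962, 0, 1, 99.95, 100.00, 0.05, 99.95),
    ("202", 2136, 2136, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("203", 2980, 2960, 5, 20, 99.33, 99.83, 0.84, 99.16),
    ("205", 2656, 2656, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("207", 1860, 1856, 0, 4, 99.78, 100.00, 0.22, 99.78),
    ("208", 2955, 2948, 2, 7, 99.76, 99.93, 0.30, 99.70),
    ("209", 3005, 3002, 2, 3, 99.90, 99.93, 0.17, 99.83),
    ("210", 2650, 2634, 3, 16, 99.40, 99.89, 0.72, 99.28),
    ("212", 2748, 2748, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("213", 3251, 3242, 2, 9, 99.72, 99.94, 0.34, 99.66),
    ("214", 2262, 2256, 1, 6, 99.73, 99.96, 0.31, 99.69),
    ("215", 3363, 3357, 3, 6, 99.82, 99.91, 0.27, 99.73),
    ("217", 2208, 2200, 5, 8, 99.64, 99.77, 0.59, 99.41),
    ("219", 2154, 2150, 1, 4, 99.81, 99.95, 0.23, 99.77),
    ("220", 2048, 2048, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("221", 2427, 2413, 9, 14, 99.42, 99.63, 0.95, 99.06),
    ("222", 2483, 2483, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("223", 2605, 2587, 9, 18, 99.31, 99.65, 1.04, 98.97),
    ("228", 2053, 2034, 6, 19, 99.07, 99.71, 1.22, 98.79),
    ("230", 2256, 2256, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("231", 1571, 1571, 0, 0, 100.00, 100.00, 0.00, 100.00),
    ("232", 1780, 1780, 1, 0, 100.00, 99.94, 0.06, 99.94),
    ("233", 3079, 3053, 7, 26, 99.16, 99.77, 1.07, 98.93),
    ("234", 2753, 2752, 0, 1, 99.96, 100.00, 0.04, 99.96),
]

#: Pooled MIT-BIH row: (total, tp, fp, fn, sen, ppr, der, acc).
MITDB_OVERALL_ROW = (105078, 104837, 99, 241, 99.77, 99.91, 0.32, 99.68)

#: Pooled INCART row in the same layout.
INCART_ROW = (175914, 175660, 189, 254, 99.86, 99.89, 0.25, 99.75)
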