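"""Published validation counts for the shipped five-disease rule library.

The development study of these algorithms chart-reviewed every flagged
incident case in a regional Chinese EHR platform (2010-2021) and reported,
per component algorithm and per final composite, the valid (flagged) and
confirmed (flagged and adjudicated yes) counts together with sensitivity and
PPV and their 95% binomial CIs.  Those counts are data inputs here: the
evaluation module recomputes every printed metric from them.

``TRUE_CASES`` holds the per-disease gold-standard denominators, which the
published table does not print directly; each was back-solved from
confirmed/sensitivity and verified consistent across every row of its
disease block.  The published IBD row 12 sensitivity (18.64) is inconsistent
with its own counts (32/59 = 54.24; row 11's value appears to have been
repeated) and is marked ``sen_anomaly`` — reproduction checks skip the
printed sensitivity for that row.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceRow", "TRUE_CASES", "REFERENCE_ROWS", "reference_rows"]

#: Gold-standard true-case denominators per disease (back-solved, verified).
TRUE_CASES = {"hashimoto": 117, "ibd": 59, "itp": 56, "ra": 30, "t1d": 44}


@dataclass(frozen=True)
class ReferenceRow:
    disease: str
    algorithm: str          # component number as a string, or "final"
    valid: int
    confirmed: int
    sen: float | None       # printed sensitivity %, None where printed NA
    sen_ci: tuple | None
    ppv: float | None
    ppv_ci: tuple | None
    sen_anomaly: bool = False

    @property
    def true_cases(self) -> int:
        return TRUE_CASES[self.disease]


def _r(disease, algorithm, valid, confirmed, sen, sen_ci, ppv, ppv_ci, anomaly=False):
    return ReferenceRow(disease, algorithm, valid, confirmed, sen, sen_ci, ppv,
                        ppv_ci, anomaly)


REFERENCE_ROWS = [
    # Hashimoto's thyroiditis (true cases: 117)
    _r("hashimoto", "1", 13, 13, 11.11, (5.42, 16.81), 100.00, (100.00, 100.00)),
    _r("hashimoto", "2", 3, 3, 2.56, (0.00, 5.43), 100.00, (100.00, 100.00)),
    _r("hashimoto", "3", 116, 114, 97.44, (94.57, 100.00), 98.28, (95.91, 100.00)),
    _r("hashimoto", "4", 98, 97, 82.91, (76.08, 89.73), 98.98, (96.99, 100.00)),
    _r("hashimoto", "5", 17, 17, 14.53, (8.14, 20.92), 100.00, (100.00, 100.00)),
    _r("hashimoto", "6", 17, 17, 14.53, (8.14, 20.92), 100.00, (100.00, 100.00)),
    _r("hashimoto", "final", 116, 114, 97.44, (94.57, 100.00), 98.28, (95.91, 100.00)),
    # Inflammatory bowel disease (true cases: 59)
    _r("ibd", "1", 6, 6, 10.17, (2.46, 17.88), 100.00, (100.00, 100.00)),
    _r("ibd", "2", 0, 0, None, None, None, None),
    _r("ibd", "3", 30, 25, 42.37, (29.76, 54.98), 83.33, (70.00, 96.67)),
    _r("ibd", "4", 4, 3, 5.08, (0.00, 10.69), 75.00, (32.57, 100.00)),
    _r("ibd", "5", 18, 13, 22.03, (11.46, 32.61), 72.22, (51.53, 92.91)),
    _r("ibd", "6", 17, 12, 20.34, (10.07, 30.61), 70.59, (48.93, 92.25)),
    _r("ibd", "7", 67, 35, 59.32, (46.79, 71.86), 52.24, (40.28, 64.20)),
    _r("ibd", "8", 69, 35, 59.32, (46.79, 71.86), 50.72, (38.93, 62.52)),
    _r("ibd", "9", 19, 16, 27.12, (15.77, 38.46), 84.21, (67.81, 100.00)),
    _r("ibd", "10", 19, 16, 27.12, (15.77, 38.46), 84.21, (67.81, 100.00)),
    _r("ibd", "11", 11, 11, 18.64, (8.71, 28.58), 100.00, (100.00, 100.00)),
    _r("ibd", "12", 43, 32, 18.64, (8.71, 28.58), 74.42, (61.38, 87.46), anomaly=True),
    _r("ibd", "final", 67, 47, 79.66, (69.39, 89.93), 70.15, (59.19, 81.11)),
    # Primary immune thrombocytopenia (true cases: 56)
    _r("itp", "1", 4, 4, 7.14, (0.40, 13.89), 100.00, (100.00, 100.00)),
    _r("itp", "2", 2, 2, 3.57, (0.00, 8.43), 100.00, (100.00, 100.00)),
    _r("itp", "3", 4, 3, 5.36, (0.00, 11.25), 75.00, (32.57, 100.00)),
    _r("itp", "4", 0, 0, None, None, None, None),
    _r("itp", "5", 29, 21, 37.50, (24.82, 50.18), 72.41, (56.15, 88.68)),
    _r("itp", "6", 33, 23, 41.07, (28.19, 53.96), 69.70, (54.02, 85.38)),
    _r("itp", "7", 8, 5, 8.93, (1.46, 16.40), 62.50, (28.95, 96.05)),
    _r("itp", "8", 12, 5, 8.93, (1.46, 16.40), 41.67, (13.77, 69.56)),
    _r("itp", "9", 31, 22, 39.29, (26.49, 52.08), 70.97, (54.99, 86.95)),
    _r("itp", "10", 23, 19, 33.93, (21.53, 46.33), 82.61, (67.12, 98.10)),
    _r("itp", "11", 10, 8, 14.29, (5.12, 23.45), 80.00, (55.21, 100.00)),
    _r("itp", "12", 6, 5, 8.93, (1.46, 16.40), 83.33, (53.51, 100.00)),
    _r("itp", "final", 50, 35, 62.50, (49.82, 75.18), 70.00, (57.30, 82.70)),
    # Rheumatoid arthritis (true cases: 30)
    _r("ra", "1", 17, 15, 50.00, (32.11, 67.89), 88.24, (72.92, 100.00)),
    _r("ra", "2", 2, 2, 6.67, (0.00, 15.59), 100.00, (100.00, 100.00)),
    _r("ra", "3", 39, 30, 100.00, (100.00, 100.00), 76.92, (63.70, 90.15)),
    _r("ra", "4", 36, 29, 96.67, (90.24, 100.00), 80.56, (67.63, 93.48)),
    _r("ra", "5", 30, 25, 83.33, (70.00, 96.67), 83.33, (70.00, 96.67)),
    _r("ra", "6", 29, 24, 80.00, (65.69, 94.31), 82.76, (69.01, 96.51)),
    _r("ra", "final", 39, 30, 100.00, (100.00, 100.00), 76.92, (63.70, 90.15)),
    # Type 1 diabetes (true cases: 44)
    _r("t1d", "1", 13, 11, 25.00, (12.21, 37.79), 84.62, (65.00, 100.00)),
    _r("t1d", "2", 1, 1, 2.27, (0.00, 6.68), 100.00, (100.00, 100.00)),
    _r("t1d", "3", 2, 1, 2.27, (0.00, 6.68), 50.00, (0.00, 100.00)),
    _r("t1d", "4", 2, 1, 2.27, (0.00, 6.68), 50.00, (0.00, 100.00)),
    _r("t1d", "5", 44, 31, 70.45, (56.97, 83.94), 70.45, (56.97, 83.94)),
    _r("t1d", "6", 0, 0, None, None, None, None),
    _r("t1d", "7", 0, 0, None, None, None, None),
    _r("t1d", "8", 218, 38, 86.36, (76.22, 96.50), 17.43, (12.40, 22.47)),
    _r("t1d", "9", 20, 14, 31.82, (18.06, 45.58), 70.00, (49.92, 90.08)),
    _r("t1d", "10", 14, 13, 29.55, (16.06, 43.03), 92.86, (79.37, 100.00)),
    _r("t1d", "11", 2, 2, 4.55, (0.00, 10.70), 100.00, (100.00, 100.00)),
    _r("t1d", "12", 15, 14, 31.82, (18.06, 45.58), 93.33, (80.71, 100.00)),
    _r("t1d", "final", 50, 37, 84.09, (73.28, 94.90), 74.00, (61.84, 86.16)),
]

#: Final-composite membership per disease, by component number.
FINAL_MEMBERSHIP = {
    "hashimoto": [1, 2, 3, 4, 5, 6],
    "ibd": [1, 3, 5, 6, 9, 10, 11, 12],
    "itp": [1, 2, 3, 5, 9, 10, 11, 12],
    "ra": [1, 2, 3, 4, 5, 6],
    "t1d": [1, 2, 5, 10, 11, 12],
}


def reference_rows(disease: str | None = None) -> list[ReferenceRow]:
    if disease is None:
        return list(REFERENCE_ROWS)
    return [r for r in REFERENCE_ROWS if r.disease == disease]
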