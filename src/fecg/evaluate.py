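"""Beat-to-beat comparison of detected vs annotated fetal QRS.

A detected beat and an annotated beat may be paired when they lie within a
matching tolerance of each other (50 ms for fetal QRS; the 150 ms adult
interval is available as ``ADULT_TOL``).  The matching is one-to-one and
optimal: it maximises the number of pairs and, among maximum matchings,
minimises the total absolute time offset.  Because both sequences live on a
line, an optimal matching exists that never crosses, so an O(n·m) dynamic
program over the two sorted sequences finds it exactly.

From the counts: Se = TP/(TP+FN), PPV = TP/(TP+FP), ACC = TP/(TP+FP+FN) and
F1 = 2·TP/(2·TP+FN+FP) (the harmonic mean of Se and PPV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import NamedTuple

import numpy as np

from .qrs import PeakSet

__all__ = ["Metrics", "DetectionReport", "match_beats", "metrics",
           "round_half_up", "FETAL_TOL", "ADULT_TOL"]

FETAL_TOL = 0.05
ADULT_TOL = 0.15


class Metrics(NamedTuple):
    """Detection metrics as fractions in [0, 1]; None where undefined."""

    Se: float | None
    PPV: float | None
    ACC: float | None
    F1: float | None


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal round-half-up, matching printed-table conventions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def metrics(TP: int, FP: int, FN: int) -> Metrics:
    """Se/PPV/ACC/F1 from counts; undefined ratios are None, never 0."""
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be nonnegative")
    se = TP / (TP + FN) if TP + FN > 0 else None
    ppv = TP / (TP + FP) if TP + FP > 0 else None
    acc = TP / (TP + FP + FN) if TP + FP + FN > 0 else None
    f1 = 2 * TP / (2 * TP + FN + FP) if 2 * TP + FN + FP > 0 else None
    return Metrics(Se=se, PPV=ppv, ACC=acc, F1=f1)


def _match_dp(d: np.ndarray, a: np.ndarray, tol_samples: float):
    """Optimal non-crossing one-to-one matching of two sorted index arrays.

    Lexicographic objective: maximise pair count, then minimise Σ|Δ|.
    Returns the matched (detected_ordinal, annotated_ordinal) pairs.
    """
    n, m = d.size, a.size
    INF = float("inf")
    # dp[i][j] = (negative pair count, total |delta|) using d[:i], a[:j]
    dp = [[(0, 0.0)] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = min(dp[i - 1][j], dp[i][j - 1])
            delta = abs(float(d[i - 1]) - float(a[j - 1]))
            if delta <= tol_samples:
                prev = dp[i - 1][j - 1]
                cand = (prev[0] - 1, prev[1] + delta)
                if cand < best:
                    best = cand
            dp[i][j] = best
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        here = dp[i][j]
        if here == dp[i - 1][j]:
            i -= 1
        elif here == dp[i][j - 1]:
            j -= 1
        else:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
    pairs.reverse()
    return pairs


def match_beats(detected: PeakSet, annotated: PeakSet,
                tol: float = FETAL_TOL):
    """One-to-one matching of detections to annotations within ``tol`` s.

    Returns (TP, FP, FN, pairs) where pairs holds (detected_index,
    annotated_index) sample-index pairs.  Raises on a sampling-rate
    mismatch.
    """
    if detected.fs != annotated.fs:
        raise ValueError(
            f"sampling rate mismatch: {detected.fs} vs {annotated.fs}")
    tol_samples = tol * detected.fs
    ords = _match_dp(detected.indices, annotated.indices, tol_samples)
    pairs = [(int(detected.indices[i]), int(annotated.indices[j]))
             for i, j in ords]
    TP = len(pairs)
    FP = len(detected) - TP
    FN = len(annotated) - TP
    return TP, FP, FN, pairs


@dataclass
class DetectionReport:
    """Matched/unmatched beat counts with derived detection metrics."""

    TP: int
    FP: int
    FN: int
    pairs: list[tuple[int, int]] = field(default_factory=list)
    tol: float = FETAL_TOL

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")
        if self.pairs and len(self.pairs) != self.TP:
            raise ValueError("TP must equal the number of pairs")

    @classmethod
    def from_peaks(cls, detected: PeakSet, annotated: PeakSet,
                   tol: float = FETAL_TOL) -> "DetectionReport":
        TP, FP, FN, pairs = match_beats(detected, annotated, tol)
        return cls(TP=TP, FP=FP, FN=FN, pairs=pairs, tol=tol)

    @property
    def metrics(self) -> Metrics:
        return metrics(self.TP, self.FP, self.FN)

    # convenience accessors
    @property
    def Se(self): return self.metrics.Se
    @property
    def PPV(self): return self.metrics.PPV
    @property
    def ACC(self): return self.metrics.ACC
    @property
    def F1(self): return self.metrics.F1

    def to_dict(self) -> dict:
        m = self.metrics
        return {"F1": m.F1, "PPV": m.PPV, "SE": m.Se, "ACC": m.ACC,
                "TP": self.TP, "FP": self.FP, "FN": self.FN,
                "tol": self.tol}

    def to_csv_row(self, ndigits: int = 4) -> str:
        """One CSV row in printed-table column order: F1,PPV,SE,ACC,TP,FP,FN."""
        m = self.metrics
        vals = [m.F1, m.PPV, m.Se, m.ACC]
        cells = ["" if v is None else f"{round_half_up(v, ndigits):.{ndigits}f}"
                 for v in vals]
        cells += [str(self.TP), str(self.FP), str(self.FN)]
        return ",".join(cells)
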