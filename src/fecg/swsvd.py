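"""Reference formation: smooth window + SVD (SWSVD).

The adaptive canceller needs a reference morphologically similar to the
maternal ECG as it appears *on the abdomen*.  Instead of a thoracic lead,
the reference x̂(n) is synthesised from the abdominal channel itself:

* **QRS windows** ([r − W1, r + W2] around each maternal R peak): the last N
  beat segments are stacked R-aligned into an N×W matrix (W = W1 + W2 + 1)
  and the current beat is replaced by its row in the rank-q truncated-SVD
  reconstruction — the projection onto the dominant beat subspace tracks
  beat-to-beat maternal morphology drift while rejecting fetal and noise
  energy.
* **Inter-QRS stretches**: a centered moving average whose length M(i)
  equals L in the segment interior and ramps down linearly (1, 3, 5, …, L)
  towards each QRS-window boundary, so the smoothed estimate meets the SVD
  estimate without jitter at the seams.  M(i) is always odd and the
  averaging window never crosses into a QRS window.

Default geometry (at 1000 Hz): W1 = 40, W2 = 60 samples, N = 20 beats,
L = 31 samples (the smoothing length tracks the fetal QRS duration, about
26–61 ms; an odd count is required for a symmetric window), q = 2 — the
dominant component carries the mean beat shape and the second absorbs the
leading drift/alignment mode of the beat ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qrs import PeakSet

__all__ = [
    "BeatMatrix", "SmoothSpec", "ReferenceSignal",
    "build_beat_matrix", "estimate_qrs", "smooth_inter_qrs",
    "build_reference", "InsufficientHistoryError",
]

# segment_map codes
PASSTHROUGH = 0
QRS_ESTIMATED = 1
INTER_SMOOTHED = 2
SEGMENT_LABELS = {PASSTHROUGH: "passthrough",
                  QRS_ESTIMATED: "qrs_estimated",
                  INTER_SMOOTHED: "inter_smoothed"}


class InsufficientHistoryError(ValueError):
    """Raised when fewer beats than required are available for the matrix."""


@dataclass
class BeatMatrix:
    """N×W matrix of R-aligned maternal QRS segments.

    Row n holds samples [r − W1, r + W2] of its beat, so every R peak lies
    in column W1; rows are ordered by time with the current beat last.
    """

    Y: np.ndarray
    W1: int
    W2: int
    r_indices: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.r_indices = np.asarray(self.r_indices, dtype=np.int64)
        if self.Y.ndim != 2:
            raise ValueError("Y must be a matrix")
        if self.Y.shape[1] != self.W1 + self.W2 + 1:
            raise ValueError(
                f"W = W1 + W2 + 1 violated: {self.Y.shape[1]} columns vs "
                f"W1={self.W1}, W2={self.W2}"
            )
        if self.Y.shape[0] != self.r_indices.size:
            raise ValueError("one R index per row required")

    @property
    def W(self) -> int:
        return self.W1 + self.W2 + 1

    @property
    def N(self) -> int:
        return self.Y.shape[0]


@dataclass(frozen=True)
class SmoothSpec:
    """Interior moving-average length L (odd sample count)."""

    L: int = 31

    def __post_init__(self) -> None:
        if self.L < 1 or self.L % 2 == 0:
            raise ValueError(f"L must be odd and >= 1, got {self.L}")


@dataclass
class ReferenceSignal:
    """Estimated maternal ECG x̂(n) on the input grid, with provenance."""

    x_hat: np.ndarray
    segment_map: np.ndarray

    def __post_init__(self) -> None:
        self.x_hat = np.asarray(self.x_hat, dtype=float)
        self.segment_map = np.asarray(self.segment_map, dtype=np.int8)
        if self.x_hat.shape != self.segment_map.shape:
            raise ValueError("x_hat and segment_map must share a shape")
        if not np.all(np.isfinite(self.x_hat)):
            raise ValueError("reference contains non-finite values")

    def __len__(self) -> int:
        return self.x_hat.size


def _complete_beats(n_samples: int, peaks: np.ndarray,
                    W1: int, W2: int) -> np.ndarray:
    """Ordinals of beats whose [r-W1, r+W2] window lies inside the record."""
    ok = (peaks - W1 >= 0) & (peaks + W2 < n_samples)
    return np.flatnonzero(ok)


def build_beat_matrix(signal: np.ndarray, peaks: PeakSet, W1: int, W2: int,
                      N: int, t: int) -> BeatMatrix:
    """Stack the N most recent complete beats up to and including beat t.

    ``t`` is an ordinal into ``peaks.indices``.  Raises
    :class:`InsufficientHistoryError` when beat t is incomplete (window
    clipped by a record edge) or fewer than N complete beats are available.
    """
    signal = np.asarray(signal, dtype=float)
    if not 0 <= t < len(peaks):
        raise IndexError(f"beat ordinal {t} out of range")
    complete = _complete_beats(signal.size, peaks.indices, W1, W2)
    if t not in complete:
        raise InsufficientHistoryError(
            f"beat {t} window exceeds record bounds"
        )
    avail = complete[complete <= t]
    if avail.size < N:
        raise InsufficientHistoryError(
            f"beat {t}: {avail.size} complete beats available, {N} required"
        )
    chosen = avail[-N:]
    rs = peaks.indices[chosen]
    Y = np.stack([signal[r - W1: r + W2 + 1] for r in rs])
    return BeatMatrix(Y=Y, W1=W1, W2=W2, r_indices=rs)


def estimate_qrs(Y: BeatMatrix | np.ndarray, q: int) -> np.ndarray:
    """Current-beat QRS estimate: last row of the rank-q SVD reconstruction.

    A degenerate all-zero matrix returns zeros.  ``q`` must satisfy
    1 <= q <= min(N, W); q = min(N, W) reproduces the raw segment exactly.
    """
    A = Y.Y if isinstance(Y, BeatMatrix) else np.asarray(Y, dtype=float)
    if not 1 <= q <= min(A.shape):
        raise ValueError(f"q={q} outside [1, {min(A.shape)}]")
    if not A.any():
        return np.zeros(A.shape[1])
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    recon = (U[:, :q] * s[:q]) @ Vt[:q]
    return recon[-1]


def _qrs_windows(n_samples: int, peaks: np.ndarray,
                 W1: int, W2: int) -> list[tuple[int, int]]:
    """Clipped, merged half-open [start, stop) QRS windows in time order."""
    raw = [(max(0, int(r) - W1), min(n_samples, int(r) + W2 + 1))
           for r in peaks]
    merged: list[tuple[int, int]] = []
    for start, stop in raw:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], stop))
        else:
            merged.append((start, stop))
    return merged


def _smooth_segment(seg: np.ndarray, L: int) -> np.ndarray:
    """Variable-window centered mean over one inter-QRS segment.

    M(i) = min(L, 2·dl + 1, 2·dr + 1) where dl/dr are the distances to the
    segment edges — this realises the odd-valued 1, 3, …, L taper at each
    edge and caps the window so it never leaves the segment (hence never
    crosses into a QRS window).
    """
    n = seg.size
    if n < 3:
        return seg.copy()
    i = np.arange(n)
    half = (L - 1) // 2
    h = np.minimum(half, np.minimum(i, n - 1 - i))
    csum = np.concatenate(([0.0], np.cumsum(seg)))
    return (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)


def smooth_inter_qrs(signal: np.ndarray, peaks: PeakSet, W1: int, W2: int,
                     spec: SmoothSpec | None = None) -> np.ndarray:
    """Smooth every inter-QRS stretch with the variable-length window.

    Returns a full-length copy in which samples outside all QRS windows are
    replaced by the centered mean of M(i) neighbours; QRS-window samples are
    untouched.  Segments shorter than 3 samples pass through unchanged.
    """
    spec = spec or SmoothSpec()
    signal = np.asarray(signal, dtype=float)
    if len(peaks) == 0:
        raise ValueError("peaks must be non-empty")
    out = signal.copy()
    windows = _qrs_windows(signal.size, peaks.indices, W1, W2)
    # complement intervals of the merged QRS windows
    edges = [0] + [e for w in windows for e in w] + [signal.size]
    for k in range(0, len(edges), 2):
        start, stop = edges[k], edges[k + 1]
        if stop - start <= 0:
            continue
        out[start:stop] = _smooth_segment(signal[start:stop], spec.L)
    return out


def build_reference(signal: np.ndarray, peaks: PeakSet,
                    N: int = 20, W1: int = 40, W2: int = 60,
                    L: int = 31, q: int = 2) -> ReferenceSignal:
    """Assemble the full maternal reference x̂(n) for a record.

    QRS windows are filled with the rank-q SVD estimate over a per-beat
    sliding matrix of the N most recent complete beats.  During warm-up
    (fewer than N beats so far) the same estimator runs on the shorter
    matrix with the rank capped at one below the row count — capping keeps
    the reconstruction strictly truncated, so fetal and noise energy in the
    current beat is still rejected; a lone first beat passes through raw.
    Inter-QRS stretches are filled by :func:`smooth_inter_qrs`.
    ``segment_map`` records the provenance of every sample.
    """
    signal = np.asarray(signal, dtype=float)
    if len(peaks) == 0:
        raise ValueError("no maternal peaks: cannot build a reference")
    spec = SmoothSpec(L=L)
    x_hat = smooth_inter_qrs(signal, peaks, W1, W2, spec)
    seg_map = np.full(signal.size, INTER_SMOOTHED, dtype=np.int8)
    for start, stop in _qrs_windows(signal.size, peaks.indices, W1, W2):
        seg_map[start:stop] = PASSTHROUGH  # refined below per beat

    complete = _complete_beats(signal.size, peaks.indices, W1, W2)
    rows: list[np.ndarray] = []
    for count, t in enumerate(complete, start=1):
        r = int(peaks.indices[t])
        seg = signal[r - W1: r + W2 + 1]
        rows.append(seg)
        if count >= 2:
            Y = np.stack(rows[-N:])
            est = estimate_qrs(Y, min(q, Y.shape[0] - 1))
        else:
            # single beat: raw passthrough, already in x_hat
            x_hat[r - W1: r + W2 + 1] = seg
            continue
        x_hat[r - W1: r + W2 + 1] = est
        seg_map[r - W1: r + W2 + 1] = QRS_ESTIMATED
    return ReferenceSignal(x_hat=x_hat, segment_map=seg_map)
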