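"""Classical single-channel maternal-ECG cancellation baselines.

All four methods share the same cycle geometry: a maternal cycle spans
0.25 s before to 0.45 s after the detected R peak (0.7 s total).  Each
estimates the maternal contribution to a cycle from neighbouring cycles and
subtracts it; samples outside every cycle window pass through unchanged, and
the first cycle is never subtracted against an empty template.

* ``cerutti``  — running mean of up to N preceding cycles, scaled by one
  least-squares factor γ per cycle.
* ``kanjial``  — rank-1 SVD of blocks of 20 R-aligned cycles; the dominant
  component is the maternal estimate, the row residual is the fetal part.
* ``suzanna``  — like Cerutti but with separate least-squares scales for the
  P, QRS and T segments of the averaged template.
* ``vullings`` — each cycle predicted as a ridge-stabilised least-squares
  combination of its m = 7 predecessors.

When consecutive R peaks are closer than the 0.7 s window the later cycle's
subtraction extent is truncated at the midpoint between the peaks so no
sample is subtracted twice.
"""

from __future__ import annotations

import numpy as np

from .qrs import PeakSet

__all__ = ["cerutti", "kanjial", "suzanna", "vullings",
           "CYCLE_PRE", "CYCLE_POST"]

#: cycle window relative to the R peak, seconds
CYCLE_PRE = 0.25
CYCLE_POST = 0.45
#: half-width of the QRS segment for segmented scaling, seconds
QRS_HALF = 0.05
#: ridge factor for near-singular normal equations
RIDGE = 1e-8


def _cycles(n_samples: int, peaks: np.ndarray, fs: float):
    """Complete cycles as (r, start, stop, sub_start, sub_stop).

    (start, stop) is the full half-open template window; (sub_start,
    sub_stop) is the subtraction extent truncated at midpoints between
    adjacent R peaks to avoid double subtraction under overlap.
    """
    pre = int(round(CYCLE_PRE * fs))
    post = int(round(CYCLE_POST * fs))
    out = []
    for j, r in enumerate(peaks):
        r = int(r)
        start, stop = r - pre, r + post + 1
        if start < 0 or stop > n_samples:
            continue
        sub_start, sub_stop = start, stop
        if j > 0:
            sub_start = max(sub_start, (int(peaks[j - 1]) + r) // 2 + 1)
        if j + 1 < peaks.size:
            sub_stop = min(sub_stop, (int(peaks[j + 1]) + r) // 2 + 1)
        out.append((r, start, stop, sub_start, sub_stop))
    return out, pre, post


def _peaks_array(m_peaks: PeakSet | np.ndarray) -> np.ndarray:
    return m_peaks.indices if isinstance(m_peaks, PeakSet) else \
        np.asarray(m_peaks, dtype=np.int64)


def cerutti(aecg: np.ndarray, m_peaks: PeakSet | np.ndarray, fs: float,
            N: int = 20) -> np.ndarray:
    """Scaled running-template subtraction.

    The template is the mean of up to N preceding cycles; the scale
    γ = ⟨template, cycle⟩ / ⟨template, template⟩ minimises the squared
    subtraction error.  A zero-energy template yields γ = 0 (no
    subtraction).
    """
    aecg = np.asarray(aecg, dtype=float)
    peaks = _peaks_array(m_peaks)
    if peaks.size < 2:
        raise ValueError("at least 2 maternal beats required")
    out = aecg.copy()
    cycles, _, _ = _cycles(aecg.size, peaks, fs)
    history: list[np.ndarray] = []
    for r, start, stop, sub_start, sub_stop in cycles:
        y = aecg[start:stop]
        if history:
            template = np.mean(history[-N:], axis=0)
            tt = float(template @ template)
            gamma = float(template @ y) / tt if tt > 0 else 0.0
            est = gamma * template
            lo, hi = sub_start - start, sub_stop - start
            out[sub_start:sub_stop] = y[lo:hi] - est[lo:hi]
        history.append(y)
    return out


def kanjial(aecg: np.ndarray, m_peaks: PeakSet | np.ndarray, fs: float,
            block: int = 20) -> np.ndarray:
    """Blockwise rank-1 SVD cancellation.

    Complete cycles are stacked R-aligned in blocks of ``block`` rows; the
    dominant singular component of each block is the maternal estimate and
    is subtracted row-wise.  A final partial block with at least 2 rows is
    processed on its own; a single leftover cycle joins the previous block.
    """
    aecg = np.asarray(aecg, dtype=float)
    peaks = _peaks_array(m_peaks)
    if peaks.size < 2:
        raise ValueError("at least 2 maternal beats required")
    out = aecg.copy()
    cycles, _, _ = _cycles(aecg.size, peaks, fs)
    if len(cycles) < 2:
        return out
    # partition into blocks of `block`, merging a trailing singleton
    bounds = list(range(0, len(cycles), block))
    if len(cycles) - bounds[-1] == 1 and len(bounds) > 1:
        bounds.pop()
    for bi, lo in enumerate(bounds):
        hi = bounds[bi + 1] if bi + 1 < len(bounds) else len(cycles)
        group = cycles[lo:hi]
        X = np.stack([aecg[s:e] for _, s, e, _, _ in group])
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        resid = X - np.outer(U[:, 0] * s[0], Vt[0])
        for row, (_, start, stop, sub_start, sub_stop) in zip(resid, group):
            a, b = sub_start - start, sub_stop - start
            out[sub_start:sub_stop] = row[a:b]
    return out


def _segment_slices(pre: int, post: int, fs: float):
    """P / QRS / T tiling of the 0.7 s template, half-open sample slices."""
    h = int(round(QRS_HALF * fs))
    w = pre + post + 1
    return [slice(0, pre - h), slice(pre - h, pre + h + 1), slice(pre + h + 1, w)]


def suzanna(aecg: np.ndarray, m_peaks: PeakSet | np.ndarray, fs: float,
            N: int = 20) -> np.ndarray:
    """Segment-wise scaled template subtraction.

    The averaged template is split into P (0.2 s preceding the QRS), QRS
    (±0.05 s around R) and T (0.4 s following the QRS) segments; each gets
    its own least-squares scale.  Because the segments tile the template
    without overlap the block least-squares problem decouples into three
    scalar projections.  A zero-energy segment gets scale 0.
    """
    aecg = np.asarray(aecg, dtype=float)
    peaks = _peaks_array(m_peaks)
    if peaks.size < 2:
        raise ValueError("at least 2 maternal beats required")
    out = aecg.copy()
    cycles, pre, post = _cycles(aecg.size, peaks, fs)
    slices = _segment_slices(pre, post, fs)
    history: list[np.ndarray] = []
    for r, start, stop, sub_start, sub_stop in cycles:
        y = aecg[start:stop]
        if history:
            template = np.mean(history[-N:], axis=0)
            est = np.zeros_like(template)
            for sl in slices:
                seg = template[sl]
                ss = float(seg @ seg)
                scale = float(seg @ y[sl]) / ss if ss > 0 else 0.0
                est[sl] = scale * seg
            lo, hi = sub_start - start, sub_stop - start
            out[sub_start:sub_stop] = y[lo:hi] - est[lo:hi]
        history.append(y)
    return out


def vullings(aecg: np.ndarray, m_peaks: PeakSet | np.ndarray, fs: float,
             m: int = 7) -> np.ndarray:
    """Linear-prediction template subtraction.

    Each cycle is predicted as a weighted combination of its (up to) m
    preceding cycles; the weights solve the ridge-stabilised normal
    equations (X Xᵀ + ridge·I) w = X y, where the rows of X are the
    predecessor cycles and y is the current cycle.
    """
    aecg = np.asarray(aecg, dtype=float)
    peaks = _peaks_array(m_peaks)
    if peaks.size < 2:
        raise ValueError("at least 2 maternal beats required")
    out = aecg.copy()
    cycles, _, _ = _cycles(aecg.size, peaks, fs)
    history: list[np.ndarray] = []
    for r, start, stop, sub_start, sub_stop in cycles:
        y = aecg[start:stop]
        if history:
            X = np.stack(history[-m:])
            G = X @ X.T
            ridge = RIDGE * max(np.trace(G), 1.0)
            w = np.linalg.solve(G + ridge * np.eye(G.shape[0]), X @ y)
            est = w @ X
            lo, hi = sub_start - start, sub_stop - start
            out[sub_start:sub_stop] = y[lo:hi] - est[lo:hi]
        history.append(y)
    return out
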