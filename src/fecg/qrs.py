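"""QRS detection: maternal R peaks (Pan–Tompkins) and fetal R peaks.

The maternal detector follows the classic Pan–Tompkins chain: 5–15 Hz
band-pass, derivative, squaring, 150 ms moving-window integration, adaptive
dual thresholds with search-back and a 200 ms refractory period.  Each
detection is then snapped to the local absolute-amplitude maximum of the
input signal within ±40 ms, so timestamps land on R apexes (the input is
expected to be band-limited already, e.g. by
:func:`fecg.preprocess.bandpass`), and finally refined by cross-correlation
against the average beat template to suppress apex jitter.

The fetal detector operates on an extraction residual: it thresholds a
smoothed energy envelope (squared signal, 80 ms moving average) at a fixed
fraction (default 0.42) of a running envelope scale — the 95th percentile of
the envelope over a sliding 5 s window — with a 0.15 s refractory period.
The threshold is relative, so detections are invariant to amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .io import EcgRecord

__all__ = ["PeakSet", "detect_maternal", "detect_fetal"]

#: Pan–Tompkins refractory period (s)
PT_REFRACTORY = 0.2
#: snap-to-apex search half-width (s)
SNAP_HALFWIDTH = 0.04


@dataclass
class PeakSet:
    """Strictly increasing 0-based R-peak sample indices on one time grid."""

    indices: np.ndarray
    fs: float
    kind: str = "maternal"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.kind not in ("maternal", "fetal"):
            raise ValueError(f"unknown peak kind {self.kind!r}")

    def __len__(self) -> int:
        return self.indices.size

    def times(self) -> np.ndarray:
        """Peak times in seconds."""
        return self.indices / self.fs


def _snap_to_apex(x: np.ndarray, idx: np.ndarray, half: int) -> np.ndarray:
    """Move each index to the |x| maximum within +-half samples."""
    out = np.empty_like(idx)
    for i, p in enumerate(idx):
        lo = max(0, p - half)
        hi = min(x.size, p + half + 1)
        out[i] = lo + int(np.argmax(np.abs(x[lo:hi])))
    return out


def _enforce_refractory(idx: np.ndarray, score: np.ndarray,
                        min_gap: float) -> np.ndarray:
    """Greedy highest-score-first selection with a minimum index gap."""
    order = np.argsort(score)[::-1]
    kept: list[int] = []
    for j in order:
        p = int(idx[j])
        if all(abs(p - k) >= min_gap for k in kept):
            kept.append(p)
    return np.sort(np.asarray(kept, dtype=np.int64))


def detect_maternal(record: EcgRecord) -> PeakSet:
    """Detect maternal R peaks with the Pan–Tompkins algorithm.

    Requires fs >= 200 Hz and at least 2 s of signal (the adaptive
    thresholds are initialised from the first 2 s of the integrated
    waveform).  Returns possibly-empty, strictly increasing indices with
    gaps of at least 200 ms.
    """
    fs = record.fs
    if fs < 200:
        raise ValueError(f"maternal detection requires fs >= 200 Hz, got {fs}")
    x = record.samples
    if x.size < 2 * fs:
        raise ValueError("record shorter than 2 s")

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv ** 2
    mwi = uniform_filter1d(sq, size=max(1, int(round(0.150 * fs))),
                           mode="nearest")

    refr = int(round(PT_REFRACTORY * fs))
    cand, _ = sps.find_peaks(mwi, distance=refr)
    if cand.size == 0:
        return PeakSet(np.array([], dtype=np.int64), fs, "maternal")

    # adaptive dual thresholds on the integrated signal
    init = mwi[: int(2 * fs)]
    spki = float(init.max()) * 0.4        # running signal-peak estimate
    npki = float(np.mean(init)) * 0.5     # running noise-peak estimate
    accepted: list[int] = []
    rr_history: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < cand.size:
        p = int(cand[i])
        peak = mwi[p]
        if peak > threshold1():
            if accepted:
                rr_history.append(p - accepted[-1])
                if len(rr_history) > 8:
                    rr_history.pop(0)
            accepted.append(p)
            spki = 0.125 * peak + 0.875 * spki
        else:
            # search-back: a long gap with no accepted beat re-examines the
            # best candidate in the gap at half threshold
            if (rr_history and accepted
                    and p - accepted[-1] > 1.66 * np.mean(rr_history)):
                gap = [int(c) for c in cand[: i + 1]
                       if accepted[-1] + refr <= c <= p]
                if gap:
                    best = max(gap, key=lambda c: mwi[c])
                    if mwi[best] > 0.5 * threshold1():
                        rr_history.append(best - accepted[-1])
                        if len(rr_history) > 8:
                            rr_history.pop(0)
                        accepted.append(best)
                        spki = 0.25 * mwi[best] + 0.75 * spki
                        i += 1
                        continue
            npki = 0.125 * peak + 0.875 * npki
        i += 1

    if not accepted:
        return PeakSet(np.array([], dtype=np.int64), fs, "maternal")
    idx = np.asarray(accepted, dtype=np.int64)
    half = int(round(SNAP_HALFWIDTH * fs))
    snapped = _snap_to_apex(x, idx, half)
    refined = _align_to_template(x, snapped, fs)
    final = _enforce_refractory(refined, np.abs(x[refined]), refr)
    return PeakSet(final, fs, "maternal")


def _align_to_template(x: np.ndarray, idx: np.ndarray, fs: float,
                       iters: int = 2) -> np.ndarray:
    """Cross-correlation refinement of beat alignment.

    Amplitude-apex timestamps jitter by a few samples under noise and
    fetal overlap; downstream beat-matrix methods are sensitive to row
    misalignment.  Each beat is shifted (within ±10 ms) to maximise its
    correlation with the average beat template, iterated twice so the
    template itself sharpens.  Beats too close to a record edge keep their
    apex timestamp.
    """
    if idx.size < 2:
        return idx
    half = int(round(SNAP_HALFWIDTH * fs))
    search = max(1, int(round(0.010 * fs)))
    shifts = np.arange(-search, search + 1)
    idx = idx.copy()
    for _ in range(iters):
        segs = [x[r - half: r + half + 1] for r in idx
                if r - half >= 0 and r + half + 1 <= x.size]
        if not segs:
            return idx
        template = np.mean(segs, axis=0)
        if not template.any():
            return idx
        new = np.empty_like(idx)
        for i, r in enumerate(idx):
            if r - half - search < 0 or r + half + search + 1 > x.size:
                new[i] = r
                continue
            scores = [x[r + s - half: r + s + half + 1] @ template
                      for s in shifts]
            new[i] = r + shifts[int(np.argmax(scores))]
        idx = np.unique(new)
    return idx


def detect_fetal(fecg: EcgRecord, threshold: float = 0.42,
                 refractory: float = 0.15) -> PeakSet:
    """Detect fetal R peaks on an extracted FECG by energy thresholding.

    Parameters
    ----------
    fecg : EcgRecord
        Extraction residual (the canceller output).
    threshold : float in (0, 1)
        Fraction of the running envelope scale a peak must exceed.
    refractory : float
        Minimum separation between detections, seconds.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if refractory <= 0:
        raise ValueError("refractory must be positive")
    x = fecg.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    fs = fecg.fs

    env = uniform_filter1d(x ** 2, size=max(1, int(round(0.080 * fs))),
                           mode="nearest")

    # running scale: 95th percentile over a sliding 5 s window, evaluated on
    # a 0.5 s hop grid and linearly interpolated per sample
    win = int(round(5.0 * fs))
    hop = max(1, int(round(0.5 * fs)))
    centers = np.arange(0, x.size, hop)
    scale_pts = np.array([
        np.percentile(env[max(0, c - win // 2): min(x.size, c + win // 2 + 1)],
                      95.0)
        for c in centers
    ])
    scale = np.interp(np.arange(x.size), centers, scale_pts)

    refr = refractory * fs
    cand, _ = sps.find_peaks(env, distance=max(1, int(np.ceil(refr))))
    cand = cand[env[cand] > threshold * scale[cand]]
    if cand.size == 0:
        return PeakSet(np.array([], dtype=np.int64), fs, "fetal")

    half = int(round(SNAP_HALFWIDTH * fs))
    snapped = _snap_to_apex(x, cand, half)
    # snapping can shrink gaps below the refractory; re-enforce it keeping
    # the stronger envelope peak
    final = _enforce_refractory(snapped, env[snapped], refr)
    return PeakSet(final, fs, "fetal")
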