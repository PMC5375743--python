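"""SWSVD reference formation: beat matrix, SVD estimate, smooth window."""

import numpy as np
import pytest

from fecg import bandpass, build_reference, detect_maternal
from fecg.qrs import PeakSet
from fecg.swsvd import (
    BeatMatrix,
    InsufficientHistoryError,
    QRS_ESTIMATED,
    SmoothSpec,
    build_beat_matrix,
    estimate_qrs,
    smooth_inter_qrs,
)

FS = 1000.0


def _eig_rank_q(Y, q):
    """Independent oracle: rank-q reconstruction via eigenvectors of Y Yᵀ.

    Projects the rows onto the span of the top q left singular directions,
    computed by a symmetric eigendecomposition rather than an SVD.
    """
    G = Y @ Y.T
    vals, vecs = np.linalg.eigh(G)
    W = vecs[:, np.argsort(vals)[::-1][:q]]
    return W @ (W.T @ Y)


# ---------------------------------------------------------------- beat matrix

def test_beat_matrix_alignment_impulse_train():
    x = np.zeros(50)
    peaks = PeakSet(np.array([10, 20, 30, 40]), FS)
    x[peaks.indices] = 7.0
    bm = build_beat_matrix(x, peaks, W1=1, W2=1, N=3, t=3)
    assert bm.Y.shape == (3, 3)
    np.testing.assert_array_equal(bm.Y[:, 1], [7.0, 7.0, 7.0])
    np.testing.assert_array_equal(bm.Y[:, 0], 0.0)


def test_window_identity():
    x = np.arange(5000.0)
    peaks = PeakSet(np.arange(100, 4900, 200), FS)
    bm = build_beat_matrix(x, peaks, W1=40, W2=60, N=20, t=len(peaks) - 1)
    assert bm.W == 101           # W = W1 + W2 + 1
    assert bm.Y.shape == (20, 101)
    with pytest.raises(ValueError, match="W = W1"):
        BeatMatrix(Y=np.zeros((2, 5)), W1=1, W2=1, r_indices=np.array([3, 9]))


def test_insufficient_history():
    x = np.zeros(5000)
    peaks = PeakSet(np.arange(100, 4900, 200), FS)
    with pytest.raises(InsufficientHistoryError):
        build_beat_matrix(x, peaks, W1=40, W2=60, N=20, t=5)


# --------------------------------------------------------------- SVD estimate

def test_rank_one_matrix_identical_rows():
    v = np.array([1.0, -2.0, 0.5, 3.0])
    Y = np.tile(v, (5, 1))
    est = estimate_qrs(Y, q=1)
    assert np.max(np.abs(est - v)) < 1e-9 * np.max(np.abs(v))


def test_full_rank_reconstruction_is_identity():
    rng = np.random.default_rng(0)
    Y = rng.standard_normal((6, 9))
    est = estimate_qrs(Y, q=6)
    np.testing.assert_allclose(est, Y[-1], atol=1e-12)


def test_exact_rank_one_example():
    Y = np.array([[1.0, 2, 0, 1], [2, 4, 0, 2], [1, 2, 0, 1]])
    est = estimate_qrs(Y, q=1)
    np.testing.assert_allclose(est, [1, 2, 0, 1], atol=1e-9)
    np.testing.assert_allclose(est, _eig_rank_q(Y, 1)[-1], atol=1e-9)


@pytest.mark.parametrize("q", [1, 2, 5, 20])
def test_agrees_with_eigendecomposition_oracle(q):
    rng = np.random.default_rng(q)
    Y = rng.standard_normal((20, 101))
    est = estimate_qrs(Y, q=q)
    np.testing.assert_allclose(est, _eig_rank_q(Y, q)[-1], atol=1e-9)


def test_degenerate_and_domain():
    assert np.array_equal(estimate_qrs(np.zeros((3, 4)), 1), np.zeros(4))
    with pytest.raises(ValueError, match="q="):
        estimate_qrs(np.zeros((3, 4)), 5)


# ------------------------------------------------------------- smooth window

def _lone_peak(n, r):
    return PeakSet(np.array([r]), FS)


def test_constant_preserved():
    x = np.full(300, 4.2)
    out = smooth_inter_qrs(x, _lone_peak(300, 150), W1=10, W2=10,
                           spec=SmoothSpec(31))
    np.testing.assert_allclose(out, 4.2)


def test_linear_ramp_preserved_in_interior():
    x = np.arange(400.0)
    out = smooth_inter_qrs(x, _lone_peak(400, 200), W1=10, W2=10,
                           spec=SmoothSpec(31))
    np.testing.assert_allclose(out, x, atol=1e-9)


def test_hand_computed_center_mean():
    # 7-sample inter-QRS segment; M=3 at its center averages [0, 9, 0] -> 3
    x = np.zeros(27)
    x[13] = 9.0
    # QRS windows [0..9] and [17..26]; segment is samples 10..16
    peaks = PeakSet(np.array([5, 21]), FS)
    out = smooth_inter_qrs(x, peaks, W1=5, W2=4, spec=SmoothSpec(3))
    assert out[13] == pytest.approx(3.0)
    np.testing.assert_array_equal(out[:10], x[:10])  # QRS windows untouched


def test_short_segment_passthrough():
    x = np.random.default_rng(0).standard_normal(30)
    peaks = PeakSet(np.array([10, 15]), FS)  # 2-sample gap between windows
    out = smooth_inter_qrs(x, peaks, W1=2, W2=1, spec=SmoothSpec(31))
    np.testing.assert_array_equal(out[12:14], x[12:14])


def test_smoothing_monotone_in_L():
    """Total variation of the smoothed segment never grows with L."""
    rng = np.random.default_rng(3)
    x = rng.standard_normal(600)
    peaks = PeakSet(np.array([50, 550]), FS)
    tv_prev = np.inf
    for L in (1, 5, 15, 31, 61):
        out = smooth_inter_qrs(x, peaks, W1=20, W2=20, spec=SmoothSpec(L))
        seg = out[71:530]
        tv = np.sum(np.abs(np.diff(seg)))
        assert tv <= tv_prev + 1e-12
        tv_prev = tv


# ------------------------------------------------------------ full reference

def test_reference_tracks_periodic_maternal(periodic_maternal):
    """On a noiseless periodic maternal-only record x_hat stays close."""
    pre = bandpass(periodic_maternal.record)
    peaks = detect_maternal(pre)
    ref = build_reference(pre.samples, peaks)
    steady = slice(20000, len(pre.samples) - 1000)
    err = np.sqrt(np.mean((ref.x_hat[steady] - pre.samples[steady]) ** 2))
    rms = np.sqrt(np.mean(pre.samples[steady] ** 2))
    assert err <= 0.05 * rms


def test_reference_continuity_at_seams(periodic_maternal):
    """Seam jumps stay comparable to in-segment jumps (no jitter spikes)."""
    pre = bandpass(periodic_maternal.record)
    peaks = detect_maternal(pre)
    ref = build_reference(pre.samples, peaks)
    jumps = np.abs(np.diff(ref.x_hat[20000:]))
    seam = np.diff(ref.segment_map[20000:].astype(int)) != 0
    assert jumps[seam].max() <= 3 * jumps[~seam].max()


def test_fetal_spikes_suppressed_in_reference(default_synth):
    """At fetal peaks clear of maternal QRS windows, the reference stays
    within half a fetal R amplitude of the true maternal waveform."""
    s = default_synth
    pre = bandpass(s.record)
    peaks = detect_maternal(pre)
    ref = build_reference(pre.samples, peaks)
    maternal_pre = bandpass(s.record.with_samples(s.mecg_clean)).samples
    fetal_pre = bandpass(s.record.with_samples(s.fecg_clean)).samples
    f_amp = np.mean(np.abs(fetal_pre[s.f_peaks.indices]))
    clear = [t for t in s.f_peaks.indices
             if np.min(np.abs(peaks.indices - t)) > 80]
    leak = np.abs(ref.x_hat[clear] - maternal_pre[clear])
    assert np.mean(leak) < f_amp / 2


def test_reference_requires_peaks():
    with pytest.raises(ValueError, match="peaks"):
        build_reference(np.zeros(1000), PeakSet(np.array([], dtype=int), FS))


def test_warmup_uses_reduced_rank(default_synth):
    """Every complete QRS window after the first beat is SVD-estimated."""
    pre = bandpass(default_synth.record)
    peaks = detect_maternal(pre)
    ref = build_reference(pre.samples, peaks)
    second = int(peaks.indices[1])
    assert np.all(ref.segment_map[second - 40: second + 61] == QRS_ESTIMATED)
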