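"""Template-subtraction baselines: exact small cases and synthetic records."""

import numpy as np
import pytest

from fecg import bandpass, cerutti, detect_maternal, kanjial, suzanna, vullings
from fecg.baselines import CYCLE_PRE, CYCLE_POST, QRS_HALF
from fecg.qrs import PeakSet
from fecg.synth import make_beat

FS = 1000.0
PRE = int(round(CYCLE_PRE * FS))
POST = int(round(CYCLE_POST * FS))
ALL_METHODS = [cerutti, kanjial, suzanna, vullings]


def _cycle_signal(cycle_scales, rr=800, rng=None):
    """Signal made of one base cycle repeated with per-cycle scale factors."""
    base, apex = make_beat("maternal", FS)
    n = rr * (len(cycle_scales) + 1)
    x = np.zeros(n)
    peaks = []
    for i, c in enumerate(cycle_scales):
        r = rr // 2 + i * rr
        x[r - apex: r - apex + base.size] += c * base
        peaks.append(r)
    return x, PeakSet(np.array(peaks), FS)


def test_cerutti_exact_scale_recovery():
    """Second cycle = 2x the first: gamma = 2 leaves a zero residual."""
    x, peaks = _cycle_signal([1.0, 2.0])
    out = cerutti(x, peaks, FS, N=20)
    r = peaks.indices[1]
    assert np.max(np.abs(out[r - PRE: r + POST + 1])) < 1e-9


def test_kanjial_identical_cycles_cancel():
    x, peaks = _cycle_signal([1.0] * 6)
    out = kanjial(x, peaks, FS, block=20)
    for r in peaks.indices[1:]:
        assert np.max(np.abs(out[r - PRE: r + POST + 1])) < 1e-9


def test_kanjial_rank_one_cycles_cancel():
    x, peaks = _cycle_signal([0.5, 1.0, 1.5, 2.0, 0.8])
    out = kanjial(x, peaks, FS, block=20)
    for r in peaks.indices:
        assert np.max(np.abs(out[r - PRE: r + POST + 1])) < 1e-8


def test_suzanna_segment_scale_recovery():
    """A cycle whose P/QRS/T blocks are scaled (2, 1, 0.5) is cancelled."""
    x, peaks = _cycle_signal([1.0, 1.0, 1.0, 1.0])
    h = int(round(QRS_HALF * FS))
    w = PRE + POST + 1
    slices = [slice(0, PRE - h), slice(PRE - h, PRE + h + 1), slice(PRE + h + 1, w)]
    r = int(peaks.indices[-1])
    window = slice(r - PRE, r + POST + 1)
    cyc = x[window].copy()
    for sl, scale in zip(slices, (2.0, 1.0, 0.5)):
        cyc[sl] *= scale
    x2 = x.copy()
    x2[window] = cyc
    out = suzanna(x2, peaks, FS)
    # subtraction extent of the last cycle is truncated at the RR midpoint
    lo = (int(peaks.indices[-2]) + r) // 2 + 1
    assert np.max(np.abs(out[lo: r + POST + 1])) < 1e-9


def test_suzanna_template_equals_cycle():
    x, peaks = _cycle_signal([1.0, 1.0])
    out = suzanna(x, peaks, FS)
    r = int(peaks.indices[1])
    lo = (int(peaks.indices[0]) + r) // 2 + 1
    assert np.max(np.abs(out[lo: r + POST + 1])) < 1e-9


def test_vullings_identical_cycles_cancel():
    x, peaks = _cycle_signal([1.0] * 9)
    out = vullings(x, peaks, FS, m=7)
    r = int(peaks.indices[-1])
    lo = (int(peaks.indices[-2]) + r) // 2 + 1
    rms = np.sqrt(np.mean(x[r - PRE: r + POST + 1] ** 2))
    assert np.sqrt(np.mean(out[lo: r + POST + 1] ** 2)) < 1e-6 * rms


def test_vullings_linear_combination_cancels():
    """A cycle that is an exact mix of its predecessors leaves ~0 residual."""
    x, peaks = _cycle_signal([1.0, 0.7, 1.3, 0.9, 1.1])
    # last cycle replaced by a linear combination of the others
    r = int(peaks.indices[-1])
    window = slice(r - PRE, r + POST + 1)
    combo = np.zeros(PRE + POST + 1)
    for rp, wgt in zip(peaks.indices[:-1], (0.1, 0.2, 0.3, 0.4)):
        combo += wgt * x[rp - PRE: rp + POST + 1]
    x2 = x.copy()
    x2[window] = combo
    out = vullings(x2, peaks, FS, m=7)
    lo = (int(peaks.indices[-2]) + r) // 2 + 1
    rms = np.sqrt(np.mean(combo ** 2))
    assert np.sqrt(np.mean(out[lo: r + POST + 1] ** 2)) < 1e-6 * rms


@pytest.mark.parametrize("method", ALL_METHODS)
def test_periodic_maternal_steady_state(method, periodic_maternal):
    """Noiseless periodic maternal-only: residual <= 2% of signal RMS."""
    pre = bandpass(periodic_maternal.record)
    peaks = detect_maternal(pre)
    out = method(pre.samples, peaks, FS)
    steady = slice(20000, len(out) - 1000)
    rms_in = np.sqrt(np.mean(pre.samples[steady] ** 2))
    rms_out = np.sqrt(np.mean(out[steady] ** 2))
    assert rms_out <= 0.02 * rms_in


@pytest.mark.parametrize("method,survival", [
    (cerutti, 0.8), (kanjial, 0.8), (vullings, 0.7),
])
def test_fetal_spikes_survive(method, survival, default_synth):
    """Fetal R peaks clear of maternal QRS keep most of their amplitude."""
    s = default_synth
    pre = bandpass(s.record)
    peaks = detect_maternal(pre)
    out = method(pre.samples, peaks, FS)
    fetal_pre = bandpass(s.record.with_samples(s.fecg_clean)).samples
    clear = [t for t in s.f_peaks.indices
             if np.min(np.abs(peaks.indices - t)) > 100]
    ratio = np.mean(np.abs(out[clear])) / np.mean(np.abs(fetal_pre[clear]))
    assert ratio >= survival


def test_suzanna_beats_cerutti_under_t_wave_drift(default_synth):
    """Independent per-wave drift favours segment-wise over global scaling."""
    s = default_synth  # default generator drifts each wave independently
    pre = bandpass(s.record)
    peaks = detect_maternal(pre)
    steady = slice(20000, len(pre.samples) - 1000)
    rms_suz = np.sqrt(np.mean(suzanna(pre.samples, peaks, FS)[steady] ** 2))
    rms_cer = np.sqrt(np.mean(cerutti(pre.samples, peaks, FS)[steady] ** 2))
    assert rms_suz <= rms_cer * 1.02


@pytest.mark.parametrize("method", ALL_METHODS)
def test_length_and_gap_passthrough(method):
    """Output length equals input; samples outside cycle windows untouched."""
    x, peaks = _cycle_signal([1.0, 1.2, 0.9, 1.1])
    out = method(x, peaks, FS)
    assert out.size == x.size
    r0 = int(peaks.indices[0])
    np.testing.assert_array_equal(out[:r0 - PRE], x[:r0 - PRE])
    tail = int(peaks.indices[-1]) + POST + 1
    np.testing.assert_array_equal(out[tail:], x[tail:])


@pytest.mark.parametrize("method", [cerutti, suzanna, vullings])
def test_first_cycle_passthrough(method):
    """Sequential methods never subtract the first cycle (empty history)."""
    x, peaks = _cycle_signal([1.0, 1.2, 0.9, 1.1])
    out = method(x, peaks, FS)
    r0 = int(peaks.indices[0])
    hi = (r0 + int(peaks.indices[1])) // 2  # untruncated part of cycle 0
    np.testing.assert_array_equal(out[r0 - PRE: hi], x[r0 - PRE: hi])


@pytest.mark.parametrize("method", ALL_METHODS)
def test_requires_two_beats(method):
    with pytest.raises(ValueError, match="2 maternal beats"):
        method(np.zeros(5000), PeakSet(np.array([1000]), FS), FS)
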