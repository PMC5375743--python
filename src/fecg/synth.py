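"""Synthetic abdominal-ECG mixtures with ground truth.

Every stage of the extraction chain is testable without any recording: the
generator produces a maternal beat train (~60–100 bpm) whose morphology
drifts smoothly from beat to beat — emulating the nonlinear propagation
from the maternal heart to the abdomen that defeats fixed-template
cancellers — a superimposed fetal beat train (~110–170 bpm) at roughly one
order of magnitude lower amplitude, sinusoidal baseline wander and
broadband sensor noise.  The stored components sum to the mixture exactly,
and the true maternal and fetal R-peak indices are recorded.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) whose centres and
widths scale with the QRS width; the waveform is normalised to unit R
amplitude.  Beat-to-beat morphology drift multiplies each bump's amplitude
and the common width by independent AR(1) processes (coefficient 0.9), so
the drift is smooth but not a global rescaling — exactly the regime where a
single per-cycle scale factor cannot track the maternal shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import EcgRecord
from .qrs import PeakSet

__all__ = ["SynthSpec", "SynthRecord", "make_beat", "synth_aecg"]

#: Gaussian bump layout relative to the QRS width w: (centre/w, amplitude, sd/w)
_WAVES = (
    ("P", -2.5, 0.12, 0.60),
    ("Q", -0.9, -0.10, 0.18),
    ("R", 0.0, 1.0, 1.0 / 2.354820045),   # sd chosen so FWHM = w
    ("S", 0.9, -0.15, 0.18),
    ("T", 3.5, 0.25, 1.20),
)
#: default QRS widths (full width at half maximum of the R bump), seconds.
#: An adult R wave rises and falls within ~30 ms (the full QRS complex,
#: Q onset to S offset, spans ~2.5x that); keeping the R bump this sharp
#: also keeps its energy above the 8 Hz preprocessing cut-off.
MATERNAL_QRS_WIDTH = 0.03
# The R-bump FWHM; the full fetal QRS complex (Q onset to S offset) spans
# about 2.5x this, so 0.02 s gives a ~50 ms fetal QRS — mid-range of the
# 26-61 ms reported across gestation.
FETAL_QRS_WIDTH = 0.02
#: AR(1) coefficient of the per-beat morphology drift
DRIFT_AR = 0.9


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic abdominal mixture.

    Amplitudes are relative to the maternal R peak (= 1).  ``morph_drift``
    is the stationary standard deviation of the per-beat AR(1) modulation
    of maternal bump amplitudes and width.
    """

    duration: float = 60.0
    fs: float = 1000.0
    maternal_hr: float = 80.0
    fetal_hr: float = 140.0
    rr_jitter: float = 0.03
    fetal_amp_ratio: float = 0.15
    morph_drift: float = 0.05
    noise_sd: float = 0.02
    wander_amp: float = 0.3
    wander_freq: float = 0.25
    fetal_qrs_width: float = FETAL_QRS_WIDTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration * self.fs < 2000:
            raise ValueError("record must span at least 2000 samples")
        if min(self.maternal_hr, self.fetal_hr, self.fs) <= 0:
            raise ValueError("rates must be positive")
        if not 0 <= self.fetal_amp_ratio <= 1:
            raise ValueError("fetal_amp_ratio must lie in [0, 1]")
        for name in ("rr_jitter", "morph_drift", "noise_sd", "wander_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SynthRecord:
    """Mixture plus its exact additive components and ground-truth peaks."""

    record: EcgRecord
    mecg_clean: np.ndarray
    fecg_clean: np.ndarray
    noise: np.ndarray
    wander: np.ndarray
    m_peaks: PeakSet
    f_peaks: PeakSet
    spec: SynthSpec = field(repr=False, default=None)

    @property
    def aecg(self) -> np.ndarray:
        return self.record.samples


def make_beat(kind: str, fs: float, qrs_width: float | None = None,
              amp_factors: dict[str, float] | None = None,
              width_factor: float = 1.0) -> tuple[np.ndarray, int]:
    """One unit-R-amplitude beat waveform.

    Returns ``(waveform, r_offset)`` where ``r_offset`` is the sample index
    of the R apex within the waveform.  ``qrs_width`` is the full width at
    half maximum of the R bump in seconds (defaults per ``kind``);
    ``amp_factors`` and ``width_factor`` apply multiplicative morphology
    modulation per bump / to all widths.  Factors are clamped to keep the
    beat physiological (amplitudes within ±3×, widths within [0.5, 2]×).
    """
    if kind not in ("maternal", "fetal"):
        raise ValueError(f"unknown beat kind {kind!r}")
    if qrs_width is None:
        qrs_width = MATERNAL_QRS_WIDTH if kind == "maternal" else FETAL_QRS_WIDTH
    w = float(qrs_width)
    wf = float(np.clip(width_factor, 0.5, 2.0))
    amp_factors = amp_factors or {}
    # support: from P tail to T tail
    left = (-2.5 - 4 * 0.60) * w * wf
    right = (3.5 + 4 * 1.20) * w * wf
    r_offset = int(np.ceil(-left * fs))
    n = r_offset + int(np.ceil(right * fs)) + 1
    t = (np.arange(n) - r_offset) / fs
    beat = np.zeros(n)
    for name, c, a, sd in _WAVES:
        af = float(np.clip(amp_factors.get(name, 1.0), -3.0, 3.0))
        beat += a * af * np.exp(-0.5 * ((t - c * w * wf) / (sd * w * wf)) ** 2)
    apex = int(np.argmax(beat))
    peak = beat[apex]
    if peak > 0:
        beat /= peak
    return beat, apex


def _beat_times(duration: float, hr: float, jitter: float,
                rng: np.random.Generator) -> np.ndarray:
    """R times in [0.5, duration − 0.5] with relative RR jitter."""
    rr = 60.0 / hr
    times = []
    t = 0.5
    while t < duration - 0.5:
        times.append(t)
        t += rr * max(0.2, 1.0 + jitter * rng.standard_normal())
    return np.asarray(times)


def synth_aecg(spec: SynthSpec | None = None, **overrides) -> SynthRecord:
    """Generate one seeded synthetic abdominal mixture.

    Keyword overrides are applied to the default :class:`SynthSpec`.  The
    same spec (seed included) always produces a bit-identical record.
    """
    if spec is None:
        spec = SynthSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))

    m_times = _beat_times(spec.duration, spec.maternal_hr, spec.rr_jitter, rng)
    f_times = _beat_times(spec.duration, spec.fetal_hr, spec.rr_jitter, rng)

    # AR(1) morphology drift: one state per bump amplitude plus one width
    wave_names = [wname for wname, *_ in _WAVES]
    innov_sd = spec.morph_drift * np.sqrt(1.0 - DRIFT_AR ** 2)
    states = {wname: 0.0 for wname in wave_names}
    width_state = 0.0

    mecg = np.zeros(n)
    m_idx = []
    for tk in m_times:
        for wname in wave_names:
            states[wname] = (DRIFT_AR * states[wname]
                             + innov_sd * rng.standard_normal())
        width_state = DRIFT_AR * width_state + innov_sd * rng.standard_normal()
        amp_factors = {wname: 1.0 + states[wname] for wname in wave_names}
        beat, apex = make_beat("maternal", spec.fs,
                               amp_factors=amp_factors,
                               width_factor=1.0 + width_state)
        # make_beat normalises the apex to 1, so reapply the overall
        # amplitude drift of the R bump on top of the relative-shape drift
        beat = beat * max(0.2, 1.0 + states["R"])
        r = int(round(tk * spec.fs))
        start = r - apex
        lo, hi = max(0, start), min(n, start + beat.size)
        mecg[lo:hi] += beat[lo - start: hi - start]
        m_idx.append(r)

    fecg = np.zeros(n)
    f_idx = []
    if spec.fetal_amp_ratio == 0:
        f_times = np.array([])  # no fetal component -> empty ground truth
    for tk in f_times:
        beat, apex = make_beat("fetal", spec.fs,
                               qrs_width=spec.fetal_qrs_width)
        r = int(round(tk * spec.fs))
        start = r - apex
        lo, hi = max(0, start), min(n, start + beat.size)
        fecg[lo:hi] += spec.fetal_amp_ratio * beat[lo - start: hi - start]
        f_idx.append(r)

    noise = spec.noise_sd * rng.standard_normal(n)
    phase = rng.uniform(0, 2 * np.pi)
    wander = spec.wander_amp * np.sin(
        2 * np.pi * spec.wander_freq * np.arange(n) / spec.fs + phase)

    aecg = mecg + fecg + noise + wander
    m_peaks = PeakSet(np.asarray(m_idx, dtype=np.int64), spec.fs, "maternal")
    f_peaks = PeakSet(np.asarray(f_idx, dtype=np.int64), spec.fs, "fetal")
    record = EcgRecord(
        samples=aecg, fs=spec.fs,
        annotations={"maternal": m_peaks.indices, "fetal": f_peaks.indices},
        meta={"source": "synthetic", "seed": str(spec.seed)},
    )
    return SynthRecord(record=record, mecg_clean=mecg, fecg_clean=fecg,
                       noise=noise, wander=wander,
                       m_peaks=m_peaks, f_peaks=f_peaks, spec=spec)
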