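"""End-to-end extraction pipeline.

preprocess → maternal QRS detection → maternal-reference formation →
cancellation → fetal QRS detection → (optional) evaluation against an
annotated fetal peak set.  The proposed method ("swsvd") forms the
reference with :mod:`fecg.swsvd` and cancels it with the RLS canceller;
the four baseline methods subtract their maternal estimate directly, so
their residual *is* the extracted FECG.

Window-geometry defaults (W1, W2, L) are stated in samples at 1000 Hz; for
other sampling rates they are derived from the equivalent durations
(0.04 s, 0.06 s, 0.031 s) unless given explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import baselines as _baselines
from .evaluate import DetectionReport, FETAL_TOL
from .io import EcgRecord
from .preprocess import BandpassSpec, bandpass
from .qrs import PeakSet, detect_fetal, detect_maternal
from .rls import extract_fecg
from .swsvd import ReferenceSignal, build_reference

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "METHODS"]

METHODS = ("swsvd", "cerutti", "kanjial", "suzanna", "vullings")


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the full chain (defaults follow the method study)."""

    method: str = "swsvd"
    f_b: float = 8.0
    f_h: float = 100.0
    filter_order: int = 5
    N: int = 20
    W1: int | None = None     # samples before R; default round(0.04 * fs)
    W2: int | None = None     # samples after R; default round(0.06 * fs)
    L: int | None = None      # smoothing length; default odd ~ round(0.031*fs)
    q: int = 2
    H: int = 20
    lam: float = 0.99
    delta: float | None = None
    fetal_threshold: float = 0.42
    refractory: float = 0.15
    match_tol: float = FETAL_TOL

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {METHODS}")

    def window_geometry(self, fs: float) -> tuple[int, int, int]:
        """(W1, W2, L) in samples for a given sampling rate."""
        w1 = self.W1 if self.W1 is not None else int(round(0.04 * fs))
        w2 = self.W2 if self.W2 is not None else int(round(0.06 * fs))
        if self.L is not None:
            L = self.L
        else:
            L = int(round(0.031 * fs))
            if L % 2 == 0:
                L += 1
        return w1, w2, L


@dataclass
class PipelineResult:
    """Everything the chain produced for one record."""

    fecg: EcgRecord
    fetal_peaks: PeakSet
    maternal_peaks: PeakSet
    preprocessed: EcgRecord
    reference: ReferenceSignal | None = None
    report: DetectionReport | None = None


def run_pipeline(record: EcgRecord,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full extraction chain on one abdominal record.

    If the record carries a ``"fetal"`` annotation set, the detections are
    evaluated against it and the result includes a
    :class:`~fecg.evaluate.DetectionReport`.  Deterministic: no randomness
    anywhere in the chain.

    Raises
    ------
    ValueError
        If the record is shorter than 2 s or no maternal beats are found.
    """
    config = config or PipelineConfig()
    if record.duration < 2.0:
        raise ValueError(
            f"record of {record.duration:.2f} s too short (need >= 2 s)")
    pre = bandpass(record, BandpassSpec(config.f_b, config.f_h,
                                        config.filter_order))
    m_peaks = detect_maternal(pre)
    if len(m_peaks) < 2:
        raise ValueError("no maternal beats found")

    w1, w2, L = config.window_geometry(record.fs)
    reference = None
    if config.method == "swsvd":
        reference = build_reference(pre.samples, m_peaks, N=config.N,
                                    W1=w1, W2=w2, L=L, q=config.q)
        result = extract_fecg(pre, reference, H=config.H, lam=config.lam,
                              delta=config.delta)
        residual = result.fecg
    else:
        fn = getattr(_baselines, config.method)
        residual = fn(pre.samples, m_peaks, record.fs)

    fecg_record = pre.with_samples(residual)
    fetal_peaks = detect_fetal(fecg_record, threshold=config.fetal_threshold,
                               refractory=config.refractory)
    report = None
    if "fetal" in record.annotations:
        truth = PeakSet(record.annotations["fetal"], record.fs, "fetal")
        report = DetectionReport.from_peaks(fetal_peaks, truth,
                                            tol=config.match_tol)
    return PipelineResult(fecg=fecg_record, fetal_peaks=fetal_peaks,
                         maternal_peaks=m_peaks, preprocessed=pre,
                         reference=reference, report=report)
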