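"""Exponentially weighted RLS adaptive noise cancellation.

The canceller fits, sample by sample, an H-tap FIR mapping from the maternal
reference x̂(n) to the abdominal recording y(n), minimising the
exponentially weighted squared error  Σᵢ λⁿ⁻ⁱ e(i)²  (forgetting factor
λ ∈ (0, 1]).  The filter output x′(n) = ωᵀu(n) is the maternal component it
can explain; the residual e(n) = y(n) − x′(n) is the extracted fetal ECG.

The recursion is the standard inverse-correlation-matrix RLS:

    k  = P u / (λ + uᵀ P u)
    e  = y − ωᵀ u
    ω' = ω + k e
    P' = (P − k uᵀ P) / λ

initialised with ω = 0 and P = δ⁻¹ I.  With λ = 1 this reproduces, exactly,
the ridge-regularised batch least-squares solution (δ I + Σ u uᵀ)⁻¹ Σ u y at
every step.  Defaults: H = 20 taps, λ = 0.99, δ = 0.01 × reference variance.

By default the tap vector includes the current reference sample,
u(n) … u(n−H+1) (H taps total), so the identity mapping is representable and
a reference equal to the target cancels to machine precision; a strictly
causal delay line u(n−1) … u(n−H) is available via ``include_current=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EcgRecord
from .swsvd import ReferenceSignal

__all__ = ["RlsState", "ExtractionResult", "rls_init", "rls_step",
           "extract_fecg"]

#: rescale P when trace(P) exceeds this multiple of its initial value.
#: With λ < 1 and a narrowband (poorly exciting) reference the classic
#: recursion suffers covariance wind-up — P grows without bound in the
#: unexcited directions and the coefficients wander.  Capping the trace at
#: its initial value bounds the adaptation gain; with λ = 1 the trace is
#: nonincreasing, so the cap never binds and the exact batch least-squares
#: equivalence is preserved.
TRACE_CAP_FACTOR = 1.0


@dataclass
class RlsState:
    """Coefficients ω, inverse correlation matrix P, and hyper-parameters."""

    omega: np.ndarray
    P: np.ndarray
    lam: float
    H: int
    n: int = 0
    delta: float = 1.0
    variant: str = "ewrls"
    reinit_count: int = 0
    _trace0: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        if self._trace0 == 0.0:
            self._trace0 = float(np.trace(self.P))


def rls_init(H: int, lam: float = 0.99, delta: float = 0.01,
             variant: str = "ewrls") -> RlsState:
    """Fresh filter state: ω = 0, P = δ⁻¹ I.

    ``variant`` selects the update rule: ``"ewrls"`` (default) is the
    exponentially weighted recursion that minimises the stated cost;
    ``"literal"`` applies the recursion exactly as printed in the source
    method description (growing-window correlation update without λ, and a
    subtractive coefficient step) — kept only for comparison, it does not
    minimise the weighted cost and is not used by the pipeline.

    Raises on H < 1, λ outside (0, 1] or δ <= 0.
    """
    if H < 1:
        raise ValueError(f"filter order must be >= 1, got {H}")
    if not 0 < lam <= 1:
        raise ValueError(f"forgetting factor must lie in (0, 1], got {lam}")
    if delta <= 0:
        raise ValueError(f"regulariser delta must be positive, got {delta}")
    if variant not in ("ewrls", "literal"):
        raise ValueError(f"unknown variant {variant!r}")
    return RlsState(omega=np.zeros(H), P=np.eye(H) / delta,
                    lam=float(lam), H=int(H), delta=float(delta),
                    variant=variant)


def rls_step(state: RlsState, u_vec: np.ndarray, y: float) -> tuple[float, RlsState]:
    """One RLS update; returns the a-priori residual and the updated state.

    The state is updated in place (and also returned).  P is kept symmetric
    by averaging with its transpose; if trace(P) exceeds its initial value
    it is rescaled down (wind-up guard, counted in ``state.reinit_count``;
    see ``TRACE_CAP_FACTOR``).
    """
    u = np.asarray(u_vec, dtype=float)
    if u.shape != (state.H,):
        raise ValueError(f"tap vector must have shape ({state.H},)")
    if not (np.all(np.isfinite(u)) and np.isfinite(y)):
        raise ValueError("non-finite input to rls_step")
    e = float(y - state.omega @ u)
    Pu = state.P @ u
    if state.variant == "literal":
        # printed recursion: growing-window Sherman-Morrison update of R^-1
        # (no forgetting factor) and a subtractive coefficient step
        P = state.P - np.outer(Pu, Pu) / (1.0 + u @ Pu)
        state.P = (P + P.T) / 2
        state.omega = state.omega - (state.P @ u) * e
    else:
        k = Pu / (state.lam + u @ Pu)
        state.omega = state.omega + k * e
        P = (state.P - np.outer(k, Pu)) / state.lam
        state.P = (P + P.T) / 2
        cap = TRACE_CAP_FACTOR * state._trace0
        tr = float(np.trace(state.P))
        if tr > cap:
            state.P *= cap / tr
            state.reinit_count += 1
    state.n += 1
    return e, state


@dataclass
class ExtractionResult:
    """Canceller output: residual (FECG), fitted maternal part, final state.

    ``fecg + fitted`` equals the target sample-wise by construction.
    """

    fecg: np.ndarray
    fitted: np.ndarray
    state_final: RlsState


def extract_fecg(aecg: EcgRecord, reference: ReferenceSignal | np.ndarray,
                 H: int = 20, lam: float = 0.99,
                 delta: float | None = None,
                 include_current: bool = True) -> ExtractionResult:
    """Cancel the maternal reference from an abdominal record.

    Parameters
    ----------
    aecg : EcgRecord
        Target signal y(n).
    reference : ReferenceSignal or ndarray
        Estimated maternal ECG on the same grid (same length).
    H, lam : int, float
        Filter order and forgetting factor.
    delta : float, optional
        P-initialisation regulariser; default 0.01 × reference variance,
        which makes the extraction equivariant under joint rescaling of
        reference and target.
    include_current : bool
        Include u(n) as tap 0 (default); otherwise strictly causal
        u(n−1) … u(n−H).
    """
    ref = reference.x_hat if isinstance(reference, ReferenceSignal) else \
        np.asarray(reference, dtype=float)
    y = aecg.samples
    if ref.size != y.size:
        raise ValueError(
            f"reference length {ref.size} != record length {y.size}")
    if delta is None:
        var = float(np.var(ref))
        delta = 0.01 * var if var > 0 else 0.01
    state = rls_init(H, lam, delta)
    start = 0 if include_current else 1
    # zero-padded delay line: u(n-start), ..., u(n-start-H+1)
    padded = np.concatenate([np.zeros(start + H - 1), ref])
    fecg = np.empty_like(y)
    for n in range(y.size):
        u = padded[n: n + H][::-1]  # ref[n-start], ..., ref[n-start-H+1]
        e, state = rls_step(state, u, float(y[n]))
        fecg[n] = e
    fitted = y - fecg
    return ExtractionResult(fecg=fecg, fitted=fitted, state_final=state)
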