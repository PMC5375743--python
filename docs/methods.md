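# Methods

## Problem and signal model

An abdominal recording y(n) is modelled as y = x + f + v: maternal ECG x,
fetal ECG f (~10× weaker at the R peak), and disturbances v (baseline
wander, broadband sensor noise).  MECG and FECG overlap spectrally, so the
separation must exploit temporal structure: the maternal beat is
quasi-periodic, but its morphology drifts from beat to beat because the
heart-to-abdomen propagation is nonlinear.  That drift is what defeats both
fixed templates and thoracic-reference cancellers, and it is the regime the
whole design targets.

## Preprocessing

Two cascaded 5th-order Butterworth sections — high-pass at f_b = 8 Hz,
low-pass at f_h = 100 Hz — each applied forward–backward (`sosfiltfilt`),
giving a squared magnitude response and exactly zero phase, so R-peak
positions are not shifted.  The high cut removes noise above the QRS band;
the low cut deliberately sits far above the diagnostic 0.05 Hz convention
because the goal is QRS detection, not morphology: it removes wander and
most maternal P/T energy, which sharpens the fetal QRS against its
background.  Reflective padding of 16 cycles of the cut-off frequency
(16·fs/f_b samples) is used per section; the much shorter library default
leaves visible edge transients for an 8 Hz section at 1000 Hz and breaks
the time-reversal symmetry property the tests assert at 1e-9.  Records
must exceed the padding length (≥ ~2 s at the defaults).

## Maternal R-peak detection

Classic Pan–Tompkins: 5–15 Hz band-pass, derivative, squaring, 150 ms
moving-window integration, adaptive dual thresholds (initialised from the
first 2 s), search-back at 1.66× the running RR mean, 200 ms refractory.
Two refinements matter downstream:

* the detection timestamp is snapped to the absolute-amplitude maximum of
  the *input* signal within ±40 ms — the internal 5–15 Hz band inverts the
  wide R lobe into Q/S extrema and is unreliable for apex location;
* apexes are then aligned by cross-correlation with the average beat
  template (±10 ms, two iterations).  Under noise and maternal–fetal
  overlap the raw apex jitters by several samples; every beat-matrix
  method downstream is sensitive to row misalignment, and this step was
  the single largest contributor to end-to-end accuracy in development.

## Reference formation (smooth window + SVD)

QRS windows `[r − W₁, r + W₂]`, W₁ = 40 and W₂ = 60 samples at 1000 Hz
(scaled by fs otherwise), W = W₁ + W₂ + 1.  The N = 20 most recent beats
form an N×W matrix; the current beat's row of the rank-q reconstruction is
the QRS estimate.  The subspace projection passes what is common and
slowly varying across beats (the maternal complex and its drift) and
rejects what is idiosyncratic to one beat (fetal overlap, noise).

**Choice of q.**  q = 2 by default.  The drifting beat ensemble is not
rank-1: amplitude drift of the individual waves and residual ±1-sample
alignment jitter populate a second component (empirically the leading
drift/shift mode).  With q = 1 the in-window reference error is comparable
to a fetal R peak and produces false detections clustered at maternal
beats; q = 2 removes them; q ≥ 4 starts absorbing the overlapping fetal
QRS itself and costs sensitivity.  The parameter is exposed.

**Warm-up.**  While fewer than N beats have accumulated, the same
estimator runs on the short matrix with rank min(q, rows − 1).  The cap
keeps the reconstruction strictly truncated (a full-rank reconstruction
would return the raw beat, fetal included).  A plain running mean was
rejected: it cannot absorb the apex shifts of overlap beats and produced
the largest reference errors of the whole record during the first seconds.

**Inter-QRS smoothing.**  Between QRS windows the reference is a centered
moving average of M(i) points, M(i) = L = 31 in the interior and ramping
through the odd values 1, 3, …, L over the first and last ⌈L/2⌉ samples of
each segment (closed form M(i) = min(L, 2·d + 1) with d the distance to
the nearer segment edge, which also guarantees the window never crosses
into a QRS window).  L tracks the fetal QRS duration (26–61 ms across
gestation; 31 samples ≈ 31 ms at 1000 Hz, and the stated even value 30 is
bumped to the next odd number, as symmetric averaging needs odd M).  The
taper exists to avoid seam jitter between the smoothed and SVD-estimated
segments, which the canceller would otherwise amplify into residual
spikes.  A literal reading of the taper's index ranges places it inside
the QRS window, where the SVD estimate overwrites every sample and the
taper would be a no-op; the implementation therefore tapers just inside
each inter-QRS segment, and no alternative switch is shipped.

## Adaptive cancellation (RLS)

H = 20 taps, λ = 0.99, double precision.  The recursion is the standard
exponentially weighted RLS that exactly minimises Σ λⁿ⁻ⁱ e(i)² with ridge
initialisation P(0) = δ⁻¹I, δ = 0.01 × reference variance (scale-aware:
the extraction is equivariant under joint rescaling of reference and
target).  The tap vector includes the current reference sample u(n) by
default so that the identity mapping — and hence exact self-cancellation —
is representable; a strictly causal delay line is available.

Numerical safeguards: P is symmetrised every step, and its trace is capped
at its initial value.  The cap addresses covariance wind-up: the SWSVD
reference is narrowband, excitation is nonstationary (large in QRS
windows, small between), and with λ < 1 the uncapped P grows by orders of
magnitude in the unexcited directions, letting the coefficients wander and
spraying residual bursts at window seams.  For λ = 1 the trace is
nonincreasing, so the cap never binds and the recursion remains exactly
equivalent to regularised batch least squares (asserted against a
normal-equations oracle in the tests).  The recursion exactly as printed
in the source description (growing-window correlation update without the
forgetting factor, subtractive coefficient step) is available as
`variant="literal"` for comparison only; it does not minimise the stated
cost.

The extracted FECG is the canceller residual e(n); the filter output is
the maternal fit, and residual + fit reconstructs the input to machine
precision.

Known behaviour: part of the fetal energy unavoidably leaks into the
smoothed inter-QRS reference (a moving average only attenuates, never
removes, a bump of comparable width), so the extracted fetal R amplitude
is typically ~6 dB below the clean fetal component — far less than the
≥ 30 dB maternal suppression, which is the contrast detection relies on.

## Fetal R-peak detection

Energy envelope = 80 ms moving average of the squared residual.  The
detection threshold is relative: 0.42 × a running envelope scale, defined
as the 95th percentile of the envelope over a sliding 5 s window
(evaluated on a 0.5 s hop grid and interpolated — the full per-sample
percentile is computationally pointless at this smoothness).  Candidates
are envelope maxima at least 0.15 s apart; timestamps snap to the
absolute-amplitude maximum of the residual within ±40 ms; the refractory
period is re-enforced after snapping, keeping the stronger envelope peak.
Because the threshold is a fraction of a signal-derived scale, detection
is exactly invariant to amplitude scaling.  The 0.42/0.15 s values follow
the established fetal-detector convention; the envelope definition is this
package's own, so the threshold is implementation-relative.

## Beat matching and metrics

Matching is one-to-one within a 50 ms tolerance (150 ms is the adult
convention, exposed as `ADULT_TOL`).  The matcher is an O(n·m) dynamic
program over the two sorted peak sequences that maximises the pair count
and, among maximum matchings, minimises the total |Δt|; on a line an
optimal matching may be taken non-crossing (uncrossing two pairs never
increases either objective), so the DP is exactly optimal.  A
shortest-pair-first greedy was considered and rejected: it is not
cardinality-optimal (detected {0, 10}, annotated {9, 11}, tolerance 10
→ greedy 1 pair, optimum 2), and the tests hold the matcher to the
optimum via a Hungarian-algorithm oracle.  Metrics: Se, PPV,
ACC = TP/(TP+FP+FN) and F1; undefined ratios are reported as absent, not
zero; table comparisons round half-up to 4 decimals.

## Baselines

All four share the 0.7 s cycle window (0.25 s before to 0.45 s after R).
Overlapping windows (RR < 0.7 s) truncate the later cycle's subtraction at
the RR midpoint so no sample is subtracted twice.  Sequential methods
(Cerutti, Suzanna, Vullings) never subtract the first cycle (empty
history) and run mean/prediction over whatever history has accumulated, up
to their N = 20 / m = 7.  Suzanna's P/±0.05 s QRS/T segments tile the
template, so its segment-wise least squares decouples into three scalar
projections.  Vullings' printed normal equations are dimensionally
inconsistent; the implemented form predicts the current cycle from its m
predecessors via (XXᵀ + 1e-8·tr·I)w = Xy, the consistent ridge-stabilised
reading (the fit uses the current cycle, mildly non-causal within the
cycle, as specified).  Kanjial subtracts the rank-1 component per block of
20 cycles; a trailing partial block (≥ 2 rows) is processed alone, and a
single leftover cycle joins the previous block.

## Synthetic data generator

Beats are sums of five Gaussian bumps (P, Q, R, S, T) with centres and
widths proportional to the QRS width and unit R amplitude.  Defaults
emulate the study conditions: fs = 1000 Hz, 60 s records, maternal 80 bpm
and fetal 140 bpm with 3 % RR jitter, fetal/maternal R amplitude ratio
0.15, white noise σ = 0.02, wander 0.3 at 0.25 Hz, maternal R-bump FWHM
30 ms (an adult R wave; also keeps QRS energy above the 8 Hz cut-off) and
fetal R-bump FWHM 20 ms, putting the full fetal QRS at ~50 ms — mid-range
of the 26–61 ms gestational span.  Maternal morphology drift is an AR(1)
process (coefficient 0.9, stationary σ = 0.05) applied multiplicatively
per wave amplitude and to the common width — per-wave, not global, because
a global scale is exactly what the Cerutti baseline can cancel and real
propagation drift is not global.  Maternal–fetal QRS overlaps are not
avoided.  One seeded generator drives everything; identical specs produce
bit-identical records, and the stored components sum to the mixture
exactly.

What the simulator does not emulate: uterine EMG and electrode-motion
artifacts, ectopic beats, fetal movement/position changes, realistic
volume-conductor morphology.  Passing the synthetic suite therefore
demonstrates the mechanics of the method under controlled drift, overlap
and noise — not clinical performance.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on 60 s
records at 1000 Hz (≈ 80 maternal / 140 fetal beats), the batch-RLS
equivalence on 5000-sample streams, the SVD oracle on 20×101 matrices, and
the matcher oracle on 500 random instances with ≤ 12 beats per side.
Every random draw is seeded; the pipeline itself contains no randomness,
so extractions are bit-reproducible for a fixed record and configuration.

## Known limitations

* Fetal beats fully inside a maternal QRS window are partially absorbed by
  the subspace projection; most residual misses are of this kind.
* The fetal detector's absolute performance depends on its envelope
  definition; the 0.42 threshold is not transferable to other envelope
  conventions.
* W₁/W₂/L scale linearly with fs from their 1000 Hz defaults; very low
  sampling rates (< ~250 Hz) leave too few samples per QRS window for the
  beat matrix to be informative.
* CSV (single- or multi-column with a `# fs=` header) is the only on-disk
  format; annotations ride in the header or as one-column index files.
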