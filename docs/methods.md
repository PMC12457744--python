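# Methods

This note records the models behind `breathflow`, the parameter choices
that matter, what the simulator does and does not emulate, and the
numerical decisions a maintainer would want to know about.

## Transduction model

The sensor converts abdominal pressure to open-circuit voltage by contact
electrification. Three facts anchor the model: the static sensitivity is
bilinear (0.88 V/kPa below a 4.87 kPa breakpoint, 0.29 V/kPa above,
continuous at the knee); the waveform is biphasic (positive while the
sensor is being compressed, negative on release); and a held pressure does
not sustain a voltage — the electrode senses charge *transfer*. The
simplest model reproducing all three is a static bilinear map

    s(p) = 0.88·p                     for p ≤ 4.87 kPa
         = 0.88·4.87 + 0.29·(p−4.87)  above

followed by a first-order high-pass. The high-pass is discretised as the
charge-relaxation recursion `y[n] = exp(−dt/τ)·y[n−1] + (x[n] − x[n−1])`,
whose step response peaks at exactly the static map before decaying — so
step-calibration peaks equal s(p) to machine precision — and whose
frequency response matches the analog RC filter at low frequency. The time
constant defaults to τ = 1 s: slow enough that a 0.2 Hz breath stays a
clean biphasic swing (gain ≈ 0.78 at 0.2 Hz), fast enough to reject drift.
A `humidity_atten` factor in (0, 1] statically scales the output,
standing in for humidity-induced charge leakage; no dynamic
humidity/temperature model is attempted.

## Scenario rendering

Breathing scenarios are declarative: an ordered list of segments, each
with a rate (breaths/s), a depth (peak pressure, kPa), and a fractional
amplitude `reduction` (0 = normal, 0.47 = the canonical hypopnea,
1 = full pause). Segments render as raised-cosine pressure cycles with a
symmetric 1:1 inhale:exhale split (the least-assuming choice) and
breathing phase carried continuously across segments. Sampling defaults to
100 Hz, a typical respiration-DAQ rate and ≥ 25× the fastest 2 Hz
breathing mode.

The packaged sleep-apnea scenario breathes at 0.2 Hz with a baseline
depth of **5.095 kPa**. That number was solved for once, numerically, so
that the transduced, conditioned baseline breath amplitude is 3.5 V
peak-to-trough: the naive inversion 3.5/0.88 ≈ 4.0 kPa ignores the ≈ 0.78
high-pass gain at 0.2 Hz and would render ≈ 2.7 V. The solved depth sits
slightly above the 4.87 kPa knee; the resulting mild compression of the
voltage scale turns the programmed 47 % pressure reduction into a ≈ 45 %
voltage reduction, comfortably inside the hypopnea band. The 18 s pause is
rendered with reduction 0.90 — residual 0.35 V breaths, not silence. The
three-mode scenario uses depths 2.30 and 4.56 kPa, giving ≈ 2 V and ≈ 4 V
breath amplitudes at 1–2 Hz where the high-pass gain is ≈ 0.99.

The noise model adds, per a single integer seed: white Gaussian noise
(default sd 0.05 V), sinusoidal baseline wander (0.2 V at 0.05 Hz),
powerline pick-up (0.05 V at 50 Hz), and optional sparse biphasic
motion-artifact bursts (0.5 s, Poisson arrivals). Defaults keep the SNR
visibly high, as on the bench. The forced-exhalation generator produces
the cumulative single-breath curve `C·(1 − e^{−(t−t₀)/τ})` directly
(capacity C in volts, expiratory speed C/τ); the transformation between
the biphasic breathing waveform and this cumulative curve is not modelled.

What the simulator does **not** emulate: charge-transport physics,
inter-subject variability, posture changes, cardiac contamination,
non-stationary breathing morphology, or eating/talking artifacts. Passing
tests therefore demonstrate algorithmic correctness under the stated
signal model, not clinical performance on human recordings.

## Conditioning and breath detection

Traces are conditioned with a zero-phase Butterworth cascade, 0.05–3 Hz
by default (covering 0.1–2 Hz breathing with margin). Two numerical
choices matter: the low- and high-pass sections are designed separately
(a single band-pass with corners four decades apart is ill-conditioned),
and the 0.05 Hz high-pass is applied with padding on the scale of its own
settling time while the low-pass uses Gustafsson edge handling — without
this, forward–backward edge transients corrupt several seconds at each
end. Zero-phase filtering is non-negotiable: event durations downstream
depend on unshifted timestamps.

Breaths are positive peaks with prominence ≥ 25 % of a robust
peak-to-trough swing estimate (2nd–98th percentile spread) and spacing
≥ 0.3 s; amplitude is peak minus the minimum before the next peak. A
second detection pass runs on the signal minus its running mean over one
breath period (90th percentile of inter-peak intervals, so mixed-rate
records keep their slowest breaths): this removes the residual baseline
wander that leaks through the 0.05 Hz corner and would otherwise bias
amplitudes by a few percent — enough to matter at the 30 % hypopnea
boundary. The Morse decoder disables this pass because its breathing is
sparse and the running mean would subtract signal.

## Event scoring and AHI

Per-cycle amplitude reductions are measured against a rolling baseline:
the median of the last 10 breaths that did not themselves look event-like
(excluding in-event breaths prevents baseline collapse during long
events). The leading estimate, used until 10 normal breaths have
accumulated, is the 75th percentile of the first window — reductions pull
amplitudes down only, so the contamination from an early-starting event is
one-sided and a high percentile stays anchored to normal breathing.

Scoring combines two candidate routes. Runs of consecutive reduced
breaths (entry at ≥ 30 % reduction, persisting in both directions while
≥ 80 % of the entry threshold — hysteresis, so one breath flickering at
the boundary does not split a clinical event) are bounded by midpoints to
the surrounding normal breaths. Breath-free gaps (spacing > 2× the
typical interval) are cessation candidates; when the conditioned trace is
available their boundaries are refined at sample level by thresholding
the rolling peak-to-trough envelope (window = half a breath period) at
50 % of the baseline amplitude, with a quarter-window edge correction —
calibrated on synthetic pauses, this measures cessation durations with
≈ ±1 s error where pure peak bookkeeping errs by up to a breath period
per edge. Overlapping candidates merge. Spans ≥ 10 s survive; a surviving
event is an apnea if it contains a ≥ 10 s full cessation (or one covering
three quarters of its span) or its mean reduction is ≥ 90 %, and a
hypopnea if the mean reduction lies in the hypopnea band. Thresholds are
compared at whole-percent resolution, the same rounding the worked
percent-reduction bookkeeping uses.

The default hypopnea band is 30–90 %: the textbook definition is
30–50 %, but reductions of, say, 60 % are clinically indefensible to
discard, so the strict band is selectable (`hypopnea_hi=0.5`) rather than
default. Apnea is operationalised as ≥ 90 % amplitude reduction or absent
breaths, since airflow itself is not observable from an abdominal belt.
AHI is events per hour of recording, graded normal/mild/moderate/severe at
5/15/30. The status panel stream latches yellow (hypopnea) or red (apnea)
only once an event has persisted 10 s — online semantics — and holds to
the event's end.

On seeded random protocols (events of 12–40 s, reductions in
[0.3, 0.5] ∪ [0.9, 1.0], default noise) the pipeline recovers event
count, kind and onset (±1 breath period) in ≈ 97 % of 100 runs; the
failures are draws at the clinical boundaries (a 0.30-reduction hypopnea,
a 12 s apnea) where measurement noise makes the call genuinely ambiguous.
The test suite runs this property at 60 protocols.

## Calibration fit

`fit_piecewise` fits `v = b₀ + b₁·p + b₂·(p − c)₊` — continuous by
construction — profiling the breakpoint c on a 200-point grid between the
2nd and (n−1)th pressures and then polishing the winning cell with
bounded Brent minimisation of RSS(c), which localises a noise-free
breakpoint to better than 1e−6 kPa (the grid alone resolves ≈ 0.04 kPa).
A fit is flagged degenerate when a single line explains the data as well
as two segments, in which case the breakpoint is meaningless. The
breakpoint is treated as a free parameter throughout.

## Spirometry surrogates

Exhalation onset follows spirometry practice: back-extrapolation of the
tangent at the maximum-slope point down to the pre-rise baseline (median
of the 0.5 s before onset, resolved by a short fixed-point iteration).
The derivative is computed on a 5-point Savitzky–Golay stencil (order 2)
to keep noise out of the peak-flow surrogate; at a hard onset kink the
edge and interior stencils differ by a few percent, which bounds the
accuracy of `max_slope` on idealised curves. `v_total` is the plateau
minus baseline, `v_1s` the interpolated excursion one second after onset.
All surrogates are scale-equivariant and shift-invariant; no conversion
to litres is attempted (that requires per-subject regression against a
spirometer).

## Breath-encoded Morse

One breath per symbol: deep (4 kPa default) for a dash, shallow
(1.5 kPa) for a dot, at a 2 s breath period; silences of 1/3/7 periods
separate symbols, letters and words (the international timing convention
scaled to breath periods). The rule-based decoder clusters detected
breath amplitudes by 1-D 2-means; the split is trusted only if the
centres are separated by more than twice the within-cluster spread *and*
30 % of their midpoint (deep/shallow amplitudes differ by > 2×, while
same-depth breaths vary by a few percent), otherwise the result is
flagged low-confidence and read as all dots — an all-dash message is
genuinely undecodable without a shallow reference breath. The breath
period is estimated as half the median short inter-breath interval; a
message with no two-symbol letter has no short interval, and the decoder
falls back to the breath waveform itself (the positive lobe at 15 % of
peak height spans ≈ 0.67 of the period under default conditioning, a
constant measured once on the rendered waveform). Gaps classify at 2 and
5 periods.

Letter features are Hann-STFT log-power grids (1 s window, 0.5 s hop),
floored 60 dB below the window's own peak (keeping empty bins from
dominating distances while preserving exact log-shift under amplitude
scaling) and time-resampled to 16 columns. The classifier is multinomial
logistic regression on standardised features — small enough to train in
seconds on one CPU while exceeding the accuracy the 6-letter task
requires (≥ 95 % held-out on the default 50-per-class synthetic set with
10 % per-breath amplitude jitter and default noise). A
convolutional-recurrent variant is deliberately out of scope; the
feature-based model is the package's classifier.

## Reproducibility and problem sizes

Every stochastic operation is a pure function of its inputs and an
integer seed; the pipeline derives all stage seeds from the single
`RunConfig.seed`, and the manifest records config, seeds, package version
and output hashes. The test suite's simulation sizes (60 recovery
protocols, 50 specificity seeds, 200 round-trip messages, 100
feature-separation pairs, 50–100 Monte-Carlo calibration replicates) were
chosen so the whole suite runs in well under a minute while keeping
Monte-Carlo error far from each assertion's threshold.

## Known limitations

* Event durations from breath bookkeeping quantise at the breath period;
  the envelope refinement reduces but cannot eliminate boundary error, so
  events programmed right at the 10 s minimum or the 30 % reduction
  boundary are scored with a coin-flip's worth of measurement ambiguity.
* The SNR estimator's spectral leakage floors it at roughly 30 dB;
  anything cleaner is reported as infinite (with a warning).
* The decoder assumes one speaker and stationary deep/shallow levels; no
  adaptation, streaming, or letter segmentation by fixed windows.
* The simulator's noise is stationary and additive; real motion artifacts
  are neither.
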