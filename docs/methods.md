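# Methods

This note documents the detector's model and the design choices made
where the published description of this algorithm family leaves the
behaviour open, plus what the synthetic generator does and does not
emulate.

## Preprocessing cascade

The five stages are fixed difference equations with zero initial state;
the startup transient (first ~70 samples at 360 Hz) is accepted rather
than compensated, because the threshold stage's initialisation window
(300 samples) absorbs it.

* **Low-pass**: `y(n) = 2y(n−1) − y(n−2) + x(n) − 2x(n−6) + x(n−12)`,
  i.e. `((1−z⁻⁶)/(1−z⁻¹))²` — an 11-tap triangular FIR with DC gain 36.
  Its exact group delay is **5 samples** (symmetry center of the
  triangle), although this filter is traditionally quoted with a delay
  of 6; the delay bookkeeping uses the measured 5 so raw fiducials are
  unbiased.
* **High-pass**: the recursive form
  `y(n) = 32x(n−16) − y(n−1) + x(n) − x(n−32)` that is usually printed
  for this filter has a pole at z = −1: its impulse response rings at
  ±32 forever and its DC gain is 16, so taken literally it is not a
  high-pass at all. The recursion conflates the output with a running
  sum; the intended filter is the all-pass-minus-moving-average
  construction implemented here,
  `y(n) = 32·x(n−16) − Σ_{k=0}^{31} x(n−k)`,
  an FIR with DC gain 0 whose dominant spike (hence effective delay)
  sits at **16 samples** (traditionally quoted as 15). Together with the
  low-pass this forms the ~5–15 Hz band-pass that keeps QRS energy while
  attenuating baseline drift, powerline interference and T waves.
* **Derivative**: centered five-point slope
  `(1/8)[−x(n−2) − 2x(n−1) + 2x(n+1) + x(n+2)]`, realised causally with
  an extra 2-sample delay folded into the delay bookkeeping. Interior
  response to a unit ramp is exactly 1.
* **Squaring** makes the response polarity-free and sharpens slopes.
* **Integration**: moving-window mean over N = 24 samples (66.7 ms at
  360 Hz), normalised by 1/N as specified for this variant (the classic
  formulation omits the 1/N; the scale cancels everywhere because the
  threshold is adaptive). Group delay (N−1)/2.

Total delay 5 + 16 + 2 + 0 + 11.5 = 34.5 samples; fiducials are mapped
back by subtracting the rounded total, then snapped to the largest
absolute band-passed sample within ±50 ms (configurable;
`refine_window_ms = 0` disables). On noise-free synthetic records the
refined fiducials land within ±1 sample of the true template centers.

All sample-count constants (24, 300, 80, 400 …) are defined at 360 Hz
and rescaled by `round(n·fs/360)` for other sampling rates.

## Peak finding

The scan keeps the running maximum since the last emission and emits its
position when the signal falls below half of it. Decisions that the
published rule leaves open, resolved here:

* the running maximum restarts from the current sample after every
  emission (the half-drop rule is meaningless without a reset);
* the 300-sample forcing counter resets on every emission, forced or
  not, and the forced peak is the maximum of the whole unemitted
  stretch;
* merging closer than 80 samples keeps the larger amplitude, earlier
  position on ties, and is applied transitively (a chain of close peaks
  collapses onto its largest member);
* flat/zero stretches still emit forced peaks — rejecting them is the
  threshold stage's job, keeping this stage threshold-free.

## Adaptive threshold

`THRESHOLD = 0.25·SPK + 0.75·NPK` is recomputed after every SPK/NPK
update (a tested invariant). The refresh formula for SPK/NPK is not part
of the published description; this implementation uses the classic
exponential smoothing `est ← 0.125·peak + 0.875·est` on both, exposed as
`smoothing_factor`. Acceptance uses strict inequality
(`amplitude > THRESHOLD`), so ties reject and the decision pattern is
scale-invariant: scaling signal and state by any c > 0 leaves it
unchanged.

Search-back details:

* The timeout is `max(400 samples, 1.5·AVE_RR)` once at least one RR is
  buffered, else 400 samples; AVE_RR is the mean of the ≤10-slot FIFO
  (1.5·last-RR was the other possible reading; the buffer average is
  the only RR statistic the method defines).
* On a trigger, SPK is halved, THRESHOLD recomputed, and the candidates
  rejected since the last accepted beat are re-scanned in order; the
  first one above the lowered threshold is accepted and flagged
  `via_searchback`. Halving repeats while the gap persists and some
  pending candidate still exceeds the threshold floor `0.75·NPK`
  (below that floor no amount of halving can accept anything, which
  also guarantees termination).
* The same check runs once at the end of the signal, with the last
  sample as the gap end; otherwise a weak final beat followed by
  silence could never be recovered, since triggers are otherwise
  evaluated only when a later candidate is processed.
* SPK and NPK are floored at 0 with no upper clamp.

A consequence worth knowing: during a genuine pause (e.g. a dropped
beat) search-back will lower the threshold until *something* crosses it,
which on clean signals is typically the preceding beat's T wave. The
algorithm trades false negatives for occasional false positives inside
pauses; the abnormal-region report is robust to this (the pause still
exceeds 1000 ms), but Sp dips slightly on records with pauses.

## Reporting

Abnormal regions are RR intervals strictly greater than 1000 ms
(exactly 1000 ms is normal), measured on delay-corrected raw-signal
fiducials, reported as the full interval between the two detections
(the published form only points at the gap; the interval is the useful
generalisation). Region plots use a ±5 s context window. Lorenz output
is `x = RR(N), y = RR(N+1)` in ms, requiring ≥3 detections.

## Evaluation

Matching uses a sorted two-pointer sweep pairing each detection with the
earliest unmatched reference beat within ±150 ms. For 1-D matching with
a symmetric tolerance this greedy order achieves the maximum possible
number of pairs (nearest-first pairing does not: it can strand a
matchable neighbour), and a property test checks agreement with
exhaustive assignment on small instances. The 150 ms window is the
ANSI/AAMI EC57 convention; the method's own evaluation window is
unstated. Reference annotations are filtered to WFDB beat codes
(N L R a V F J A S E j / Q B e n f r); rhythm, quality and artifact
codes are not beats. Aggregate rates are recomputed from summed counts,
never averaged across records. `Sp` is positive predictivity
TP/(TP+FP), kept under the name this literature uses.

## Synthetic data

The generator emulates what the detector is sensitive to, not full
cardiac electrophysiology: each beat is a Gaussian QRS bump (σ = 25 ms,
within the 5–15 Hz energy band, 1 mV), a P wave (σ = 35 ms, 0.15 mV,
−160 ms) and a T wave (σ = 60 ms, 0.3 mV, +250 ms); beats start at half
the nominal RR and advance with multiplicative Gaussian RR jitter
(default 5%, floored at 0.3·RR). Noise defaults: 0.1 mV baseline drift
at 0.3 Hz, 0.05 mV powerline at 50 Hz, 0.02 mV white noise — moderate
ambulatory conditions. Dropped beats are removed wholesale after
placement (a pause has no P/QRS/T), attenuated beats scale only the QRS
bump (the search-back test case). One `numpy` generator seeded per
record; identical (spec, seed) pairs are bit-identical.

What it does not model — real QRS morphology variety (wide PVCs,
bundle-branch blocks), muscle-artifact bursts, electrode motion,
non-stationary noise — means passing tests demonstrate the state
machine's correctness and the pipeline's calibration on idealised
signals, not clinical-grade performance; benchmark-database runs remain
the arbiter of the latter.

## Problem sizes and runtime

The test suite and the acceptance script use records of 10–300 s at
360 Hz (up to ~10⁵ samples, a few hundred beats) and three 2-minute
records for the end-to-end rates — ample to exercise every code path
(initialisation, search-back, RR-buffer saturation, pauses) while the
whole suite runs in seconds. The implementation itself is linear-time
and handles half-hour 360 Hz records in well under a second per stage.

## Known limitations

* The WFDB support covers single-`.dat` records in formats 8/16/80/212
  (the MIT-BIH layout) and writes format 16 only; multiplexed
  multi-file records are rejected.
* Detection runs on one channel (the first by default); there is no
  two-channel fusion.
* The evaluation's beat-code set is the standard WFDB beat list;
  databases with unusual annotation conventions may need a custom
  filter.
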