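# Methods

## Problem and model

The package segments a defibrillator accelerometry record into
chest-compression periods and pauses. The working assumption is the one
the envelope representation encodes: while compressions are delivered, the
band-passed chest acceleration oscillates at the compression rate with a
roughly stable amplitude, so the 1 s sliding mean of its absolute value is
nearly constant and clearly positive; during pauses that envelope is
approximately zero up to noise and residual motion. Compression onsets and
offsets therefore appear as the dominant positive and negative excursions
of the envelope's smoothed derivative, and segmentation reduces to finding
an alternating sequence of those excursions and vetting the implied pauses
and periods.

## Detection chain and parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `band_low`, `band_high` | 0.2, 50 | Hz | Butterworth band edges |
| `filter_order` | 4 | – | Butterworth design order |
| `window_s` | 1.0 | s | envelope and derivative smoothing window |
| `pause_ratio` | 0.35 | – | pause/flank envelope-mean ceiling |
| `min_pause_s` | 1.6 | s | minimum accepted pause duration |
| `cc_min_level` | adaptive | internal units | period envelope floor |
| `shrink_lambda` | adaptive | units/s | soft-shrinkage threshold |
| `refine_window_s` | 1.0 | s | weighted-mean refinement window |
| `similar_max_ratio` | 0.5 | – | "similar second maximum" criterion |

Notes on the non-printed choices:

* **Filter application.** The filter is applied forward-backward
  (`sosfiltfilt`), i.e. zero phase, so markers are not systematically
  delayed against the record; a causal single pass is available via
  `zero_phase: false`. `scipy.signal.butter(4, ..., btype="bandpass")` is
  used as the design; band-pass design doubles the section count relative
  to a low-pass of the same order, which is the conventional reading of a
  "fourth-order Butterworth band-pass" in Python signal-processing code.
* **Edge handling.** All centered windows are truncated and renormalized
  at the record edges instead of padded. Padding would fabricate data
  exactly where compressions may already be ongoing at power-on/power-off;
  truncation keeps the envelope of a constant-|a| signal exact up to the
  first and last sample.
* **Derivative.** `e'` is computed by central differences (one-sided at
  the two edge samples) and smoothed with the same 1 s window as the
  envelope, keeping a single time-scale parameter for the whole chain.
* **Adaptive thresholds.** Internal accelerometer units are device
  specific and uncalibrated, so absolute defaults cannot travel across
  records. λ defaults to 10 % of the 95th percentile of the pre-shrinkage
  |d| (a robust maximum), and the period-level floor to 20 % of the 90th
  percentile of the envelope inside the candidate compression periods.
  Both accept absolute overrides. A consequence is amplitude equivariance:
  scaling a record by any positive constant leaves the segmentation
  unchanged, which the test suite asserts.
* **Rule sequencing.** The three acceptance rules are applied as: pause
  duration and pause/flank ratio first (merging one rejected pause at a
  time, innermost first in file order), then the period-level rule, with
  the whole cycle repeated until the segmentation is stable. The fixpoint
  makes the outcome insensitive to the order in which individual rejects
  are processed. When both pause rules fail, the audit record reports
  `rejected_short`.
* **Degenerate records.** If the candidate list starts with a stop marker
  (record begins mid-compression) a synthetic start is pinned to the first
  sample, and symmetrically at the end. If no candidate exists at all, the
  whole record is treated as one candidate period and the level rule
  decides: an all-zero record yields an empty segmentation (the level test
  requires a strictly positive mean), an uninterrupted compression record
  yields one wall-to-wall period.
* **Refinement.** Both start and stop markers are refined (each
  switchable). A secondary local maximum of |d| counts as "similar" when
  it reaches at least 50 % of the marker's own |d| within the 1 s centered
  window; the marker then moves to the |d|-weighted mean time of that
  window. Edge-pinned synthetic markers are never refined, and a
  refinement that would invert or overlap periods is discarded in favour
  of the unrefined position. Ties between equal extrema resolve to the
  earliest time, so adversarial flat inputs stay deterministic.

## Synthetic data

The generator renders an explicit schedule of compression bouts and pauses
into the phenomenology above: a sinusoid at the compression rate
(110 min⁻¹ by default) with amplitude 1.0 internal unit during bouts,
optional residual sinusoidal motion during pauses, a gravity offset (25
units) plus a slow drift sinusoid (amplitude 0.5 at 0.05 Hz, below the
0.2 Hz band edge), and Gaussian noise (σ = 0.02 units by default; the
`noisy` preset uses σ = 0.1, i.e. 10 % of the compression amplitude, as a
deliberately harsh noise floor). Amplitude transitions follow 0.3 s
half-cosine ramps whose midpoint is the scheduled boundary, so the
ground-truth boundary is defined to the sample and the 0.5 s recovery
tolerance used throughout the tests is meaningful. Records start at
t = 300 s to keep the "seconds since power-on" convention non-trivial.

What the generator does **not** emulate: compression-rate and depth
variability within a bout, rescuer changes, transport artefacts,
non-stationary noise, real ECG or capnography physiology (those channels
are placeholders that only satisfy the directory format), and any
device-specific unit scaling. Passing tests therefore demonstrate that the
chain implements its rules correctly and recovers boundaries under the
signal model it assumes — not clinical-grade performance on registry data.

## Numerical choices

* The 1 s window is realized as `round(window_s · fs)` samples (250 at
  250 Hz); with an even count the window is larger on the left by one
  sample, a 4 ms asymmetry that is negligible against the 0.5 s matching
  tolerance but keeps the sliding mean of a 2 Hz sinusoid at 2/π to four
  decimals (an odd 251-sample window would break the full-cycle average).
* Envelope means over intervals are computed on the envelope samples with
  `t` in `[start, stop]` inclusive; an empty interval counts as mean 0.
* Boundary markers are clipped to the record's time range, and segmentation
  validity (sorted, disjoint, start < stop) is enforced by construction of
  the `Segmentation` type.
* Segmentation files carry six decimal places; the read/write round trip
  is exact far below the 1 ms level.

## Known limitations

* The envelope of a perfectly periodic compression waveform ripples
  slightly because 1 s is not an integer number of compression cycles;
  after shrinkage this produces many tiny candidate pauses that the 1.6 s
  rule removes. They appear in the gap audit as `rejected_short` entries —
  by design the audit logs every verdict, not only interesting ones.
* Pauses shorter than the window width blur into their flanks; detected
  durations near the 1.6 s floor are accurate only to roughly the window
  time scale, and the floor is enforced on the *detected* duration.
* The pause/flank ratio is evaluated on the 1 s envelope rather than the
  raw absolute acceleration; over the same intervals the two differ only
  by edge smearing of order the window width.
* Pause classification (ventilation vs rhythm check vs shock), per-
  compression analysis, rate/depth estimation and ROSC detection are out
  of scope; the unit of output is the period.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on generated data:
46 traces of 40–45 s for the gap-duration sweep, 17 traces for the
residual-motion sweep, 50 seeded 55 s clean cases for boundary recovery,
and 200 short random series for the alternating-extrema oracle check. One
full run of everything takes well under a minute on a single core.
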