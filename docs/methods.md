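# Methods

This note records the model, the conventions the implementation fixes
where the published recipe leaves room, the synthetic-data design, and the
limitations a user should keep in mind.

## Signal model and preprocessing

The input is a beat-to-beat (RR) interval series: strictly positive
durations in seconds, with optional cumulative beat times (validated
against the cumulative intervals to within 1 ms per step). Record time is
defined from the first beat; the uniform grid starts there.

**Resampling.** Analyses operate on a uniformly sampled HRV signal at
4 Hz. The interpolation kind through the (beat time, RR) nodes is not part
of the published recipe; the default is a cubic spline (the common HRV
convention, exact on constant and linear records), with linear
interpolation available for sensitivity checks (`preprocess.interpolation`).

**Outlier replacement** is applied per analysis window, after windowing.
Two fence rules are provided:

* `multiplicative` (default, the literal reading of "1.5 times smaller
  than the 25th percentile / 1.5 times greater than the 75th"): flag
  values below Q1/1.5 or above 1.5·Q3 — meaningful for positive RR data;
* `tukey`: the symmetric Q1 − 1.5·IQR / Q3 + 1.5·IQR fences.

Flagged values are replaced by the median of the values lying within
[Q1, Q3] ("the median of the interquartile range"), which is never empty.
Quartiles use linear interpolation between order statistics (numpy's
default), fixed so fences are bit-reproducible. Replacement is a single
pass; on RR-like windows (narrow baseline plus isolated artefacts) it is
idempotent in practice, which the tests exercise, though contrived inputs
with borderline moderate outliers can be re-flagged on a second pass.

**Coarse-graining** at scale τ averages non-overlapping blocks of τ
samples; trailing samples that do not fill a block are dropped
(floor(N/τ) outputs), which reproduces the 34-sample count for a 60-s
window at 4 Hz with τ = 7. τ = 1 is the identity; composition
coarse(coarse(x, a), b) = coarse(x, ab) holds whenever ab divides N.

## The ClassA metrics

The derivative estimate is the three-point forward difference
d(n) = (4x(n+1) − 3x(n) − x(n+2))/2, implemented in the algebraically
equivalent form (3(x(n+1) − x(n)) + (x(n+1) − x(n+2)))/2 so that constant
input yields exact zeros in floating point (the degenerate SODP is then
detected exactly). The SODP holds the N − 3 points (d(n), d(n+1)), each
with its anti-clockwise angle αₙ ∈ [0°, 360°) from the positive abscissa
(two-argument arctangent; exact axis angles for exact-zero coordinates)
and a quadrant label by strict coordinate signs.

Conventions fixed here:

* **Denominator.** RAS and the quadrant proportions divide by the window
  sample count N (the published algorithm's normalisation), although the
  SODP has N − 3 points; `denominator="points"` switches to N − 3. For
  PQ3 the denominator is the coarse-grained length (34 at the published
  settings), since the quadrant count is taken on the coarse signal.
* **Axis and origin points.** Points with a zero coordinate belong to no
  quadrant (strict-sign labelling); a point on an axis but away from the
  origin still contributes its exact axis angle to RAS; origin points
  contribute nothing. How such points should be counted is not specified
  by the published recipe; exclusion avoids arbitrary double counting.
  With continuous-valued data these are measure-zero cases.
* **Trend bands.** Because the angle sum is divided by N over N − 3
  points, the decreasing band (180°, 270°) is guaranteed only for windows
  long enough that (N − 3)/N · α stays above 180° — at the published
  40-sample windows this holds comfortably. The sign of every d also
  requires successive increments a, b with b < 3a (d = (3a − b)/2); a
  strictly monotone but wildly jittered sequence can leak points into
  other quadrants. The tests therefore use monotone fixtures with bounded
  increment ratios, matching the trend-detection semantics intended for
  smooth cardiac drifts.

Invariances (verified by property tests): adding a constant or scaling by
c > 0 leaves angles, quadrant labels and all four metrics unchanged (to
floating-point rounding); negating the signal reflects the SODP through
the origin, swapping Q1↔Q3 and Q2↔Q4 counts.

## Traditional metrics

* **HR** = mean of 60/x(n) over the window (bpm) — the mean instantaneous
  rate, not 60 over the mean interval.
* **SDNN** = sample standard deviation (N − 1 denominator), in ms.
* **Spectral powers.** One-sided periodogram of the demeaned,
  Hamming-tapered window, density-normalised by the taper energy so a pure
  sinusoid of amplitude A integrates to A²/2. (Demeaning and taper-energy
  compensation are unstated in the published description, whose printed
  transform normalisation would double-normalise if applied literally; the
  implementation uses the standard periodogram.) Band powers are
  trapezoidal integrals over bins with lo ≤ f < hi, so a bin on a shared
  edge (0.15 Hz) goes to the higher band. LF = 0.04–0.15 Hz,
  HF = 0.15–0.4 Hz, Np = 0.04–0.5 Hz; nLF = 100·aLF/Np, nHF = 100·aHF/Np.
  Powers are reported in (input unit)², i.e. s² for RR in seconds —
  absolute magnitudes therefore depend on the unit convention and are not
  comparable across toolchains without care.
* **Sample entropy** (m = 2, r = 0.15·SD): Chebyshev distance,
  self-matches excluded, both template sets over the same N − m start
  indices; SE = −ln(A/B). A constant window (zero tolerance) or zero
  match count returns nan with a warning, never a silent infinity.
* **Permutation entropy** (m = 6): Shannon entropy of the ordinal-pattern
  distribution over all length-m windows, normalised by log(m!) to [0, 1].
  Rank ties are broken by order of occurrence (stable sort). A warning is
  issued when m! exceeds the window length (under-sampled distribution);
  at the 1200-sample 5-min window m = 6 satisfies m! ≤ N.

## Statistics

One omnibus Kruskal–Wallis test across the five epochs, plus separate
two-group Kruskal–Wallis tests for the two named stress contrasts
(rest vs arithmetic, meditation1 vs exercise) at α = 0.05/2 = 0.025; no
post-hoc Dunn procedure. Tie correction is always applied; p-values come
from the chi-square approximation, with an exact permutation enumeration
(total n ≤ 10) available for validation. Spearman correlations between
the four ClassA metrics and the eight traditional measures use
α = 0.05/32 = 0.0015625 (printed as 0.0016). Per-subject epoch values are
the means of the metric's sliding-window series within the epoch; the
pooling for correlations (per-epoch per-subject means) is configurable.

## Pipeline geometry

Windows step by 1 s. A window belongs to the epoch containing its start
time (default); a stricter fully-contained rule is available. Five-minute
traditional windows necessarily straddle 15-min epoch boundaries for up to
5 min after each transition — a fidelity caveat inherent to the published
window lengths, not a removable artefact. Trajectories average PQ1,
PQ2,4, PQ3 over non-overlapping 30-s blocks aligned to each epoch's start.

## Synthetic data

No public recording accompanies the method, so the generator is the test
bed. It emulates exactly the features the metrics measure and nothing
more:

    RR(t) = mean_rr + trend_slope·t + lf_amp·sin(2π·lf_freq·t)
            + hf_amp·sin(2π·hf_freq·t) + N(0, noise_sd²)   per beat

with successive beat times advanced by the current RR. Defaults: RR
0.85 s, LF 0.1 Hz at 20 ms, HF 0.3 Hz at 30 ms, beat noise 10 ms — a calm
seated adult with respiratory sinus arrhythmia and a Mayer-wave-scale LF
component. The stressed protocol parameterisation starts the arithmetic
epoch at 0.78 s with HF halved and a −2·10⁻⁴ s/s acceleration trend, and
the exercise epoch at 0.68 s with HF cut to 6 ms, damped overall
variability and a −3·10⁻⁴ s/s trend (a net ~0.2–0.3 s RR decline across a
15-min stress epoch, as seen in progressive step tests); the closing
meditation recovers with a small positive trend. These magnitudes were
fixed once, as plausible seated-stress physiology, when the generator was
designed.

What the generator does **not** emulate: integral-pulse-frequency
modulation, respiratory coupling, ectopic beats, baroreflex feedback,
1/f-scale long-memory and circadian structure. Passing tests therefore
demonstrate that the implementation recovers planted oscillations, trends
and regularity changes correctly — not that the metrics separate stress
states in real recordings.

Gaussian white beat noise is the default; the generator's per-epoch specs
can be combined freely for autocorrelated or stress-shaped variants.

## Numerical choices and problem sizes

Equality tolerances in oracle tests are 1e-9° for angles and exact
integer counts for quadrants. The pipeline's vectorised window path is
bit-identical to the per-window functions (tested). Simulated studies in
the test-suite and acceptance script use 20 batches of 10 subjects on the
full 4740-s protocol, the Kruskal–Wallis calibration 1000 null replicates
of 5 groups × 10 — sizes chosen to keep every run comfortably on one CPU
while leaving Monte-Carlo error well below the tested margins.

## Known limitations

* The multiplicative outlier fence is asymmetric and only sensible for
  positive data; use the Tukey fence for centred signals.
* PQ3's temporal scale τ = 7 is a heuristic compromise between capturing
  slow sympathetic dynamics and retaining points; no automatic scale
  selection is provided.
* Entropy metrics on 10-s windows are not meaningful (too few templates);
  the pipeline only computes them on the 5-min windows.
* Spectral absolute powers depend on the RR unit convention (s² here);
  normalised powers (nLF, nHF) are the comparable quantities.
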