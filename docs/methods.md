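# Methods

## Scope and model of the data

`myoflow` analyses time-lapse grayscale recordings of contracting
smooth-muscle tissue. The observable is a frame sequence at a nominal
2-Hz frame rate whose first frame shows the tissue relaxed; spontaneous
contraction–relaxation episodes appear as transient tissue displacement
along a roughly fixed axis: a sharp rise to a positive displacement peak
followed by a rebound past baseline to a negative peak (or the mirrored
order). The package estimates that motion, reduces it to 1-D traces,
segments the traces into events, and quantifies each event. A companion
module covers the patch-clamp read-outs used when the biological question
is ion-channel modulation of the same tissue.

All processing is deterministic; every stochastic element lives in the
synthetic-data generators and is driven by explicit seeds.

## Registration

Displacement fields are estimated by block matching: the reference frame
(always frame 0 — the relaxed state — never frame-to-frame) is tiled into
non-overlapping square blocks (default 16 px), and each block is located
in the target frame by normalized cross-correlation over a bounded search
window (default radius 10 px). The correlation peak is refined to
subpixel precision with a three-point parabolic fit per axis, with two
guards:

* the parabolic offset is clamped to ±0.5 px and skipped when the
  three-point stencil is not concave;
* refinement is skipped entirely when the peak correlation is exactly 1
  (identical content): the autocorrelation shoulders of a textured image
  are generically asymmetric, and the parabola would otherwise introduce
  a spurious offset of up to ~0.15 px at a perfect match.

Blocks with (near) zero variance cannot be matched; they report (0, 0)
and are flagged low-confidence rather than dropped, which keeps the block
grid rectangular. Displacements are signed target-relative-to-reference,
with x = columns increasing rightward and y = rows increasing downward.
Accuracy on band-limited textures is better than 0.25 px for translations
within the search radius (verified against known integer and half-pixel
warps); displacements beyond the search radius are underestimated, and
the movie generator logs a warning when it produces them.

## Flow traces

For a chosen ROI, flow strength s_i is the mean Euclidean vector norm
over the blocks whose centers fall inside the ROI; s_0 = 0 by
construction, and flow change c_i = s_i − s_{i−1} with c_0 = 0 so all
traces stay index-aligned with the stack. Smoothing is a centered moving
average with shrinking edge windows; the default window is 5 samples
(2.5 s at 2 Hz), chosen to suppress frame-level registration jitter while
leaving the ≥ 15-s event waveforms essentially untouched. Flow strength
is computed per ROI (not frame-wide), since each ROI has its own
contraction axis and phase.

## Directed velocity

The contraction axis is fitted by ordinary least squares of the smoothed
cumulative y-shift on the smoothed cumulative x-shift (the fields are
relative to frame 0, so the ROI means are already cumulative). The slope
a gives the unit direction (X, Y) = (1/L, a/L) with L = √(a² + 1), and
the projected trace is x·X + y·Y. Two conventions worth noting:

* a purely vertical axis has no finite slope in this parametrization;
  `fit_direction` then swaps the axes, regresses x on y, and builds the
  unit vector from that fit;
* the projected trace is a *displacement* per frame; the per-event
  "maximum velocity" is defined as the maximum absolute first difference
  of the raw trace divided by dt (a.u./s). Both the projection and its
  discrete derivative are exposed, so either convention can be read off.

The slope is recomputed per ROI and recording; the sign of the fitted
axis is arbitrary (a direction, not an orientation), which flips
contraction-first events into relaxation-first ones and vice versa — both
signatures are legal event shapes, so detection is unaffected.

## Event detection

Detection operates on a 1-D trace (the projected-velocity trace by
default; a configuration switch selects the smoothed flow-strength trace
instead). Stages:

1. **Baseline correction.** The trace median is subtracted. Contractions
   are episodic, so the median sits on the quiescent baseline; the
   correction is exactly zero for clean simulated traces but removes the
   small systematic offset (~0.02 px) that subpixel registration noise
   leaves on measured traces.
2. **Normalization.** Positive samples are divided by the trace maximum,
   negative samples by |minimum|, zeros preserved; the result lies in
   [−1, 1] and the operation is idempotent. An all-zero trace is
   returned unchanged with a warning.
3. **Iterative ternary peak detection.** Maximal contiguous runs above
   +0.35 (below −0.35) are registered as positive (negative) peaks and
   erased to zero; the residual is re-scanned at 0.25, then 0.15. The
   thresholds are absolute levels on the normalized trace — the extremes
   are *not* re-referenced between iterations, so "25%" always means 25%
   of the original extreme. Peak extent is exactly the supra-threshold
   run (not extended to zero crossings), which makes erasure and the
   ternary trace unambiguous; the flanks of a tall peak that fall between
   two thresholds surface as adjacent runs in later iterations and merge
   with the core in the ternary trace. Erasure is monotone: total peak
   support never decreases across iterations, and re-scanning the fully
   erased residual at the lowest threshold finds nothing.
4. **Boundary markers.** The first difference of the ternary trace gives
   an ordered marker stream: +1 entering a positive peak, −1 leaving it,
   −1 entering a negative peak, +1 leaving it. Direct ±1→∓1 transitions
   are decomposed into their leave and enter markers, so the stream
   strictly alternates peak starts and peak ends.
5. **Signature matching.** A greedy left-to-right scan pairs marker
   quadruples equal to [1, −1, −1, 1] (contraction-first) or
   [−1, 1, 1, −1] (relaxation-first) into events; consumed markers are
   never reused, and unmatched peaks are skipped whole (the scan steps in
   marker pairs, since testing quadruples at odd offsets would misread
   end markers as starts). A quadruple is accepted only if the quiescent
   gap between its two peaks is at most 10 s: in a real event the rebound
   follows its peak directly, and without the guard a one-sample noise
   peak can pair with a lobe of a distant, unrelated event and consume
   its markers. The 10-s default comfortably exceeds the widest
   inter-lobe gap a retainable (< 30 s) event can show at the lowest
   threshold (~8 s) while rejecting pairings across the ≥ 5-s
   inter-event quiescence plus sub-threshold tails.
6. **Label matching to the raw trace.** Event boundaries are extended
   outward on the raw, unsmoothed trace to the maximal sign-consistent
   support of each lobe (the walk stops at the first sample ≤ 0).
   Threshold crossings systematically start after the true lobe onset
   and stop before its offset (by roughly 20% of the event duration), so
   durations measured on marker extents alone would be biased short and
   the strict duration filter would discard genuine 16–18-s events.  On
   a clean trace the walk recovers the exact onset; under additive noise
   it stops within a sample or two of the point where the pulse falls
   below the noise. The rule assumes the metrics trace is unsmoothed —
   smoothing makes baseline noise sign-persistent and lets the walk
   wander — hence detection may run on a smoothed working copy while
   refinement and metrics always use the raw samples.
7. **Metrics and filtering.** On the refined segment of the raw trace:
   strength = trapezoidal integral of |value| (a.u.·s), maximum velocity
   = max |Δvalue|/dt (a.u./s), duration = end − start. Events are
   retained only if 15 s < duration < 30 s (strict bounds). Metrics scale
   linearly with the raw trace amplitude and are invariant to the
   normalization constant.

Counts are reported per 10-min window, linearly rescaled and flagged when
the recording length differs.

## Detector benchmarking

`evaluate_detection` matches predicted to true events one-to-one,
greedily by increasing midpoint distance, accepting pairs within ±5 s;
sensitivity = TP/(TP+FN), PPV = TP/(TP+FP) (PPV is reported as 0 with a
flag when there are no predictions). The packaged benchmark pools these
counts over 30 independent simulated recordings. The matching rule and
tolerance are package choices; a published comparison against manual
annotation of real recordings is a different experiment, so the synthetic
benchmark is an analogue of such figures, not a replication.

## Synthetic data

The generators define the study conditions and double as ground-truth
oracles:

* **Schedules.** Default 600-s recordings with 6 events per 10 min
  (benchmarks draw 4–8 per recording), durations uniform in (16, 29) s —
  strictly inside the (15, 30)-s retention band, so the duration filter
  is lossless on truth — amplitudes uniform in (0.5, 1.5) a.u., fair-coin
  polarity, and ≥ 5-s quiescent gaps between events and recording edges;
  leftover slack is spread Dirichlet-uniformly. Infeasible combinations
  raise an error.
* **Pulse shape.** Each event is two opposed raised-cosine lobes: the
  first occupies 60% of the duration with the event's amplitude, the
  second is opposite-signed and scaled (amplitude × 0.6/0.4) so the lobe
  areas cancel and the pulse integrates to zero — smooth, matching the
  described waveform, and analytically integrable.
* **Traces.** Clean pulse train plus additive zero-mean Gaussian noise
  with sd = 5% of the configuration's maximum pulse amplitude. The clean
  version is returned alongside as ground truth and is exactly zero on
  quiescent segments.
* **Movies.** A band-limited random texture (Gaussian-smoothed white
  noise, rescaled to [0, 1]) is rigidly translated along each event's
  axis with the biphasic pulse as signed magnitude, so the ground-truth
  mean displacement is exactly the 1-D clean trace; per-pixel Gaussian
  noise (sd 2% of the dynamic range) is added per frame. Warps are
  spline-interpolated, enabling subpixel oracle tests.
* **Dose–response and ramps.** Hill-shaped fold-increase tables with
  optional Gaussian noise, and ramp currents I(V) = g·(V − E_rev)·r(V)
  with a Boltzmann rectification factor r(V) = 1/(1 + exp((V − V_half)/k))
  (defaults V_half = −20 mV, k = 30 mV), giving the inward-rectifier
  asymmetry |I(−80)| > |I(+80)|.

What the simulations do *not* emulate: photorealistic tissue appearance,
non-rigid/elastic deformation within an ROI, drifting baselines,
illumination changes, multi-ROI phase relationships, and pharmacological
kinetics. Passing benchmarks therefore demonstrate the correctness of the
algorithmic chain under the stated waveform and noise model, not
performance on any particular real recording.

## Electrophysiology quantitation

Ramp currents are linearly interpolated at the requested voltage
(−80 mV by default; out-of-span requests are errors). Current density is
current/capacitance (pA/pF), capacitance serving as a surface-area proxy.
Fold increase uses magnitudes of inward currents, |treated|/|control|,
and refuses controls at the noise floor (directing the caller to current
density). Hill fits use nonlinear least squares with the baseline fixed
at 1 (control is its own normalizer), the Hill coefficient bounded to
(0.2, 6) for numerical stability without biological over-commitment, and
a free plateau; seven log-spaced half-max starting values are tried and
the best residual wins, making the fit invariant to point order. Fits are
flagged `no_response` when the plateau is within 0.05 of baseline and
`poor_fit` when r² < 0.5 (e.g. ascending data passed to the inhibition
model). Washout time courses can be exported but are not modelled.

## Statistics

The omnibus test is Kruskal–Wallis (tie-corrected, chi-square p-value);
identical-value inputs return H = 0, p = 1 with a warning. The default
post hoc is Dunn's z-test on pooled ranks with Holm adjustment; a
Tukey-HSD-on-ranks variant is provided for workflows that pair
Kruskal–Wallis with a Tukey-style procedure (that pairing is nonstandard,
which is why it is not the default). Observations are ROIs, with
recording identifiers carried through for sensitivity checks. Thin
paired/unpaired (Welch) t-test helpers cover the before/after ramp-panel
comparisons.

## Numerical and problem-size choices

Defaults: 2-Hz frame rate, 64×64-px simulated frames, 16-px blocks,
10-px search radius, 5-sample smoothing, thresholds (0.35, 0.25, 0.15),
duration bounds (15, 30) s, ±5-s matching tolerance. The packaged
benchmark uses 30 recordings of 600 s (the trace-level chain runs in
seconds); movie-based tests use 45–120-s recordings, where block matching
at these frame sizes is comfortably fast. Degenerate inputs are handled
explicitly throughout: empty ROIs, flat blocks, all-zero traces, constant
regressors, infeasible schedules and sub-noise controls all raise or flag
rather than silently misbehave.

## Known limitations

* Registration is translational per block; rotation, shear and non-rigid
  deformation inside a block degrade the correlation peak.
* The detector assumes a biphasic waveform; monophasic twitches (no
  rebound) are by construction not classified as events.
* The 10-s inter-peak gap guard and the ±5-s matching tolerance are
  package choices, stated here because published descriptions of such
  pipelines typically leave them implicit.
* OLS direction fitting assumes noise mainly in y given x; for nearly
  isotropic motion clouds the fitted axis is unstable (total least
  squares would be the upgrade path).
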