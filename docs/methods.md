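# Methods

## Component model

Each transient flash response is a phenomenological sum of smooth lobes on
a uniform grid (default 2000 samples/s, 25 ms pre-stimulus baseline,
250 ms post-stimulus epoch; time 0 = flash onset, all voltages in µV):

    V(t) = −a·G(t; μ_a, σ_a) + b·G(t; μ_b, σ_b) + w·G(t; μ_w, σ_w)
           + c·sin(2π f₀ (t − μ_op)) · G(t; μ_op, σ_op)        for t ≥ 0,

with G a unit Gaussian and V(t) = 0 before the stimulus, so the
pre-stimulus segment is an exact zero baseline. The three lobes are the
cornea-negative a-wave, the dominant positive b-wave, and the smaller
positive wavefront on the descending slope (WDS). The fourth term is the
oscillatory-potential (OP) burst: a sinusoid at f₀ = 200 Hz under a
Gaussian window (σ 5 ms) centred on the ascending limb. This is not a
biophysical retina model — no PII/PIII dynamics, no intensity–response
law; it is a ground-truthed test bed whose morphology matches dark-adapted
rabbit traces qualitatively.

### Default templates (control eye)

| condition | a (µV @ ms) | b (µV @ ms) | WDS (µV @ ms) | OP (µV) |
|---|---|---|---|---|
| DA 0.01 cd·s/m² | — | 80 @ 60 | — | — |
| DA 3 cd·s/m² | 45 @ 15 | 150 @ 38 | 15 @ **64.0** | 12 |
| DA 10 cd·s/m² | 60 @ 13.5 | 165 @ 36 | 50 @ **62.8** | 15 |
| LA 3 cd·s/m² | 8 @ 12 | 90 @ 32 | — | 5 |
| LA 10 cd·s/m² | 10 @ 12 | 110 @ 30 | — | 6 |

The two WDS latencies are the published control-eye means this package is
anchored to; their inter-animal jitter SDs (6.3 and 7.6 ms) likewise. All
amplitudes are free defaults chosen so that (i) the WDS is a clear local
maximum on the descending slope, and (ii) the b-WDS difference *decreases*
from 3 to 10 cd·s/m² (Δ ≈ 135 vs ≈ 115 µV on the noiseless templates), the
reported intensity dependence. The dim flash carries no a-wave and no WDS;
light-adapted steps carry noise-level a-waves and no WDS; flicker trains
are generated (periodic b-lobes) but not analyzed.

Two generator choices were iterated against the package's own invariants
rather than tuned freely: the OP carrier sits at 200 Hz with a 5 ms window
because a burst near 150–170 Hz leaks its lower spectral tail through the
150 Hz analysis low-pass (zero-phase |H|² ≈ 0.5–0.63 at 130–150 Hz) and
biases the measured a-trough/b-peak by 1–2 samples, breaking
oracle-equivalence; and the b-lobe width is 6 ms so that WDS latencies one
jitter-SD early still produce a discernible wavefront rather than merging
into the b descent. ≥99% of burst energy lies in the 100–300 Hz OP band
and ≥95% of lobe energy below 100 Hz, the precondition for the band-split
argument.

### Cohorts

A cohort is animals × {operated, control} × {baseline, day7, day20} ×
protocol steps. Per animal, one standard-normal draw per parameter family
is shared across eyes, sessions and steps (a stable trait): amplitudes get
lognormal multiplicative jitter (relative SD 0.15 by default), latencies
additive Gaussian jitter (1–1.5 ms; WDS per-condition as above) with
ordering-preserving clamps. The single condition effect multiplies the
operated-eye post-operative WDS amplitude by (1 − attenuation); nothing
else differs between conditions, so any a-/b-amplitude "effect" in the
output is a false positive by construction. The default attenuation 0.8
reflects severe, often complete, WDS loss after detachment.

Noise is white Gaussian (default SD 4 µV per sweep) plus optional coherent
50 Hz mains (2 µV). The averaged trace is generated directly with the
white-noise SD scaled by 1/√n_flashes; mains, being phase-locked across
sweeps of a session, is not scaled. Seeds derive from one master seed via
`SeedSequence` spawning; identical seeds give bitwise-identical cohorts.

What the generator does *not* emulate: sweep-to-sweep amplitude drift,
electrode impedance changes, photoreceptor adaptation between flashes,
eye-movement or blink artifacts, or any intensity–response continuum
between the tabulated steps. Passing tests therefore demonstrate that the
measurement chain recovers known ground truth under realistic noise — not
that it would be robust to every artifact of a live recording.

## Measurement chain

1. **Acquisition band-pass** 0.3–300 Hz (the device band), then a 150 Hz
   low-pass; both 4th-order Butterworth applied forward–backward
   (zero-phase), so peak latencies shift by at most one sample.
2. **Mains removal** (optional, on by default for cohort extraction): the
   50 Hz sine/cosine pair is fitted by least squares on the response-free
   parts of the record (pre-stimulus baseline and the tail beyond 180 ms)
   and subtracted. A narrow recursive notch is inappropriate here: its
   settling time exceeds the 275 ms epoch, leaving both residual mains and
   ringing that biases the WDS latency by about one sample.
3. **a/b metrics**: baseline = pre-stimulus mean; threshold =
   max(3 × baseline SD, 1 µV). The a-trough is the first local minimum in
   the 5–30 ms window below baseline − threshold; the b-peak is the
   maximum after the trough (after onset when the a-wave is absent — the
   convention for light-adapted steps, whose a-waves are noise-level).
   Amplitudes: a = baseline→trough, b = trough→peak. Implicit times are
   reported at sample resolution, no sub-sample interpolation.
4. **WDS detection** operates on the <100 Hz low-passed trace (6th-order
   zero-phase Butterworth — steep enough that a tone 30% above the cut
   retains <5% RMS), so OPs cannot masquerade as the WDS. Search window:
   (b_implicit + 5 ms, 120 ms]. The WDS is the local maximum of greatest
   prominence (ties → earlier peak) that clears both a prominence and a
   height threshold of max(2 µV, 6 × pre-stimulus SD of the filtered
   trace); height is referenced to the larger of the baseline and the
   late-tail median, because the zero-phase band-pass undershoot drags the
   pre-stimulus mean below the tail and would otherwise admit noise bumps
   in the undershoot valley. If no peak qualifies, a derivative-plateau
   shoulder counts: ≥5 ms with |dV/dt| under 20% of the peak descending
   slope, sitting above the height threshold, followed by a further drop —
   distinguishing a genuine inflection from terminal flatness. Otherwise
   the WDS is absent (the common outcome in operated eyes).
5. **b-WDS difference**: Δ = V(b-peak) − V(WDS), both baseline-referenced
   on the analysis-band trace. With the WDS absent, V(WDS) is read at the
   implicit time of the same eye's baseline-session WDS; if that is also
   unavailable, at the cohort-mean control latency for the step (the
   documented fallback-of-the-fallback). Δ ≥ 0 always, because the b-peak
   is the window maximum. The WDS is analyzed only in the dark-adapted 3
   and 10 cd·s/m² steps, where it occurs.
6. **Band split** (`spectral_split`): <100 Hz and 100–300 Hz branches with
   an energy report — the computational form of the OP-exclusion argument.

## Detachment-area module

Masks are binary images with the retinal disk stored as metadata; the area
fraction is simply 100 × detached pixels / disk pixels — the fundus image
is 2-D, so no correction for detachment height or retinal curvature is
attempted. The synthetic time-course fills disk pixels from the inferior
edge upward (whole rows plus one partial row), which makes every realized
area exact to one pixel, keeps regions contiguous, and nests later masks
inside earlier ones. The default course: 30% at day 0; 40% and 60%
reductions vs day 0 at days 3 and 7; "another" 70% vs day 7 at day 14
(the incremental reading of an ambiguous phrase — the baseline policy is
an explicit parameter: `day0`, `chained`, or the default mixture); empty
mask (reattached, reduction unmeasurable and reported as 100%) at day 21.

## Statistics

The design is balanced and fully within-subject, so the univariate
repeated-measures decomposition applies exactly: for each within-subject
effect E, SS are computed by subset inclusion–exclusion over cell totals
and E is tested against its subject×E interaction stratum,
F = MS_E / MS_{S×E}. SS conservation per stratum and the F(1, n−1) = t²
identity on two-level factors hold to machine precision (tested), and the
implementation is cross-checked against statsmodels' AnovaRM. No
sphericity correction is applied by default; the headline contrasts are
two-level, where sphericity is moot. Zero-variance strata are flagged
degenerate, never dropped silently. Follow-ups are two-sided paired
t-tests judged against α/k; the reporting helper truncates the threshold
to three decimals (0.05/3 → 0.016). Summaries report mean ± sample SD
(n − 1).

The default model is Δ ~ eye × session × intensity with the three
operated-vs-control timepoint comparisons at 10 cd·s/m² as follow-ups
(k = 3). "Number of repetitions" is read as the number of follow-up
comparisons; it is a parameter, not a constant.

## Problem sizes and numerical choices

Test and acceptance computations use: 551-sample traces (2000 Hz);
cohorts of 10 animals × 2 eyes × 3 sessions × 2 dark-adapted steps for the
power study (500 replicates); 2000 replicates of a 10-subject two-level
design for type-I-error calibration; 600 jittered noisy traces for
latency-recovery statistics; 512×512 masks (disk radius 230 px,
~166k disk pixels) for the area course. Dense-grid oracles evaluate the
closed-form component sum at 0.01 ms and compare extrema at sample
resolution (oracle snapped to the grid, tolerance one sample). Filters are
SOS-form Butterworth via `scipy.signal.sosfiltfilt`; the trace text format
stores full `repr` precision so round-trips are bit-exact.

## Known limitations

- The component model is additive and stationary; real WDS attenuation may
  change latency and width, not only amplitude.
- Shoulder-mode WDS latencies are read at the derivative minimum of the
  plateau and can sit several ms after the underlying lobe centre; peak
  mode carries no such bias.
- The OP carrier (200 Hz) is at the upper end of the physiological OP
  range; it was placed there so the 150 Hz analysis low-pass and the
  100–300 Hz OP band remain cleanly separable (see component model).
- The area module consumes already-binary masks; segmentation of real
  fundus photographs is out of scope.
- Flicker steps are generated for protocol completeness only; no flicker
  feature is extracted.
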