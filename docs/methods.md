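# Methods

## The kymograph representation

Axons are quasi-one-dimensional, so all analysis runs on calibrated
intensity profiles along the annotated axon path rather than on 2-D masks:
a `(frames × samples)` array sampled every pixel (0.12 μm by default) of
arc length, one per channel.  Profiles are extracted from image stacks by
taking, at each arc-length sample, the maximum over a short transect
perpendicular to the path (default ± 0.36 μm), which makes the reduction
robust to sub-pixel path annotation error.  Intervals are half-open
`[start, end)` in μm; frames are 0-based; time = frame × frame interval
(3 s by default); increasing arc length is anterograde.

Per-frame background is estimated robustly (median/MAD of the profile,
then the mean and SD of the pixels within 3 robust SDs of the median) —
mitochondria occupy a minority of the axon, so this isolates
mitochondria-free pixels without annotation.

## Segmentation and tracking

Candidate mitochondria are maximal runs of samples above background +
3 σ_background.  Because σ_background vanishes on noise-free data, every
threshold carries a floor of 2 % of the series dynamic range; this floor
is what keeps all rules well defined in the clean limit and is far below
any real signal.  Run endpoints are then refined to the *half-plateau*
crossing by linear interpolation: a uniform interval convolved with a
Gaussian PSF crosses half its plateau intensity exactly at its physical
endpoints, so segment lengths are accurate to well under a pixel for
objects longer than ~2 PSF widths.  A segment whose plateau exceeds 1.6 ×
the series' reference plateau (the median plateau over all frames) is
flagged as two spatially overlapping mitochondria — fluorescence is
additive — and excluded from length statistics while still counting
toward density (the data do not say which convention was used for
density; the flag travels with the output so either can be recomputed).

Frame-to-frame linking assigns segments greedily by maximal interval
overlap, breaking ties on the smaller mean-intensity difference;
segments without overlap are matched by nearest centre within 2.5 μm
(fast mitochondria can displace more than their own length per frame).
Unmatched appearances near a continuing track become 1→2 *split
candidates*; disappearances near a continuing track become 2→1 *merge
candidates*.  Candidates are bookkeeping, not events.

## Event criteria

A split candidate becomes a **fission** only at the first frame where
(a) the minimum intensity in the gap is ≤ background + 2 σ (with the same
dynamic-range floor) and (b) the edge-to-edge separation exceeds 0.6 μm
(5 pixels).  Constrictions that dim but re-close, or separations that
never clear 0.6 μm, are never called; the 0.6 μm bound is additionally
enforced as a construction invariant of every event record.

A merge candidate becomes a **fusion** when the merged profile is uniform
(coefficient of variation < 0.15 after smoothing with a 2-pixel Gaussian
and eroding the PSF roll-off at the ends), the merged length matches the
summed parent lengths within 2 pixels, and — when the parents' plateau
intensities differed by more than 20 % — the post-merge CV is below the
parents' between-plateau CV (intensity redistribution).  Two abutting
mitochondria of similar brightness separated by less than ~2 pixels are
indistinguishable from a fused one in principle; the simulator therefore
never produces sub-resolution non-fusion contacts (see below), and on
real data such dyads would be scored as fusion exactly as a human scorer
would.  A known limitation: a sequence "touch, then separate" between two
*equal-brightness* mitochondria would produce a split candidate whose gap
and separation criteria pass; event parents are therefore best interpreted
together with the preceding track history.

**Rates** are % of mitochondria participating as event parents per
10 min, with the denominator the population at the window start and
daughters mapped to their window-start ancestor, so a mitochondrion whose
daughter fissions again still counts once (the unit is "% of mitochondria
that underwent fission").  **Post-fission transport** is the fraction of
events with ≥ 1 child displaced > 1 μm within a horizon (60 s in the
tests) of the event.

## Motility

Detectable movement is a frame-to-frame leading-end displacement
> 0.24 μm (2 pixels); the leading end is the end facing the direction of
the step.  Classes are applied with precedence transported (> 1 μm
cumulative detectable excursion) > oscillating (detectable movement, ≤
1 μm) > stalled, which makes classification total; tracks observed less
than 1 min are unclassifiable.  Runs are maximal groups of movement steps
not interrupted by a pause ≥ 6 s (2 frames); run length sums |displacement|
regardless of direction, switches are sign changes between consecutive
movement steps, and each unidirectional bout's velocity is its
displacement over its duration.  Runs cut off by the end of observation
are marked incomplete so downstream statistics can exclude them.

## Patches, puncta and the overlap statistic

Actin patches and Drp1 accumulations share one detector: per-frame
supra-threshold spans, refined to half-peak crossings (undoing PSF
widening), linked across frames by spatial overlap; a record must persist
≥ 2 frames (single-frame flickers are rejected).  Its extent is the
refined span at its brightest frame; abutting co-active patches closer
than the PSF cannot be separated and are reported as one record.
Classification: *fission-associated* when the extent contains a fission
position and the event frame falls within ± 1 frame of the patch
lifetime; else *mito-associated* when the extent overlaps any
mitochondrion footprint while alive; else *non-mito*.  Filopodium fates
are taken from annotations or simulation truth — the pipeline does not
detect filopodia from images.

For each fission event the overlap table row is: A = parent length at the
last frame before the split, B = summed extent of actin patches active at
the call frame, clipped to the parent and union-merged so B ≤ A, and
C = B/A.  The random-overlap probability is the product of the C values,
accumulated in log₁₀.  Two dialects are always reported: `full` uses the
exact ratios, and `rounded` first rounds each C to two decimals — the
convention in force when proportions are tabulated to two decimals before
multiplication.  On the bundled 20-event reference table these give
2.34 × 10⁻²¹ and 1.75 × 10⁻²¹ respectively; the dialects genuinely differ
and only the rounded one reproduces a two-decimal table's product.  Any
C = 0 (an observed overlap with zero coverage, contradictory) zeroes the
product with a warning.  The statistic's null interpretation — C is the
chance a random site lands in a patch — is validated by simulation: with
fission sites drawn independently of patches, the observed site-in-patch
rate across hundreds of events equals the mean C within Monte-Carlo error.

## Fluorescence and FRAP

Integrated intensity is ROI area × max(mean − background, 0), with the
background the median of a user-annotated stain-free region (the median
resists bright outliers).  FRAP recovery is 100·(Iₜ − I₀)/(I_pre − I₀)
per timepoint over a fixed-length axon segment, including only traces
bleached to ≤ 10 % of baseline; recovery is 0 % at t = 0 by construction
and invariant to global gain.

## Group comparisons

Normality is tested per group with the Lilliefors-corrected KS test
(α = 0.05).  Two groups: Welch's t if both normal, else Mann-Whitney.
More than two: one-way ANOVA with Bonferroni-corrected pairwise Welch
post-hocs if all normal, else Kruskal-Wallis with Dunn's post-hoc.
Dunn's test is implemented in-house (pairwise z statistics on mean pooled
ranks with tie correction, Bonferroni-adjusted) since no installed
package provides it; it is exercised against hand-computed rank algebra
in the tests.  Categorical data use Fisher's exact test.  One-tailed p
values are available where a hypothesis dictates direction.  Corrections
are applied within a comparison family only, matching per-figure
reporting practice.

## The synthetic-axon generator

Dynamics are simulated in continuous 1-D arc length and discretised only
at render time, so truth is independent of the pixel grid.  All draws
come from fixed-offset substreams of one seeded generator; identical
configurations give identical logs.

* **Population.** Mitochondria are rigid intensity-labelled intervals
  (log-normal lengths, median 2 μm; per-mitochondrion intensities
  uniform in 70–130) placed without overlap; initial motility classes are
  drawn from configurable fractions (default 70 % stalled, 15 %
  oscillating, 15 % transported).
* **Fission.** The per-10-min probability (default 0.30, the measured
  NGF-treated rate) converts to a per-frame hazard via
  1−(1−p)^(Δt/600 s), applied to stationary mitochondria (moving
  mitochondria were not observed to fission).  The site is uniform in the
  parent interior at least 0.6 μm from each end, optionally biased toward
  actin patches (bias 1 emulates patch-mediated fission by recruiting a
  patch at the site when none is present; bias 0 is the null used to
  calibrate the overlap statistic).  Children lengths sum exactly to the
  parent.  After fission the children drift apart at 0.1 μm/frame until
  their gap reaches 0.9 μm — beyond the 0.6 μm criterion plus PSF blur —
  and with probability 0.80 per event (the measured fraction of fissions
  followed by transport) one child (both with probability 0.3) undergoes
  a committed switch-free escape run before resuming normal run-and-pause
  behaviour.  No fission is drawn in the last few frames of a movie,
  where its completion could not be observed, mirroring how events are
  scored from finite recordings.
* **Transport.** Runs draw a velocity uniform in 0.1–0.6 μm/s and a
  geometric duration (mean 8 frames); a single Bernoulli draw per run
  (default 0.55, the measured post-NGF switching fraction) decides
  whether the run contains one direction switch at a uniform position.
  Pauses are 6 s + exponential (mean 12 s total), so every inter-run
  pause satisfies the ≥ 6 s termination rule.  Velocities and pause
  durations are stated-plausible placeholders; the source measurements
  report no numeric values for them.
* **Contacts.** A moving mitochondrion approaching another either
  commits to fusion — continuing to contact and merging into a single
  interval of exactly additive length with length-weighted intensity —
  or halts with a ≥ 1 μm standoff, one decision per encounter.
  Sub-resolution non-fusion contacts therefore never occur, which is what
  makes zero-noise detection exact; the configured fusion probability is
  interpreted per contact opportunity (no pairwise kinetic constant is
  available to calibrate against).
* **Patches and puncta.** Actin patches arrive as a Poisson process in
  time and uniformly in space (default 0.05 patches/μm/min), with
  exponential durations (mean 60 s, minimum 2 frames) and log-normal
  extents (median 0.6 μm); Drp1 puncta arrive per mitochondrion (default
  2 per 10 min) with shorter durations and 0.3 μm extents, fixed in space.
  Ground-truth class labels and Bernoulli filopodium fates are logged.
* **Rendering.** Each interval becomes a box convolved analytically with
  a Gaussian PSF (σ = 0.15 μm); overlapping sources add; a constant
  background (10 counts) is added and Poisson-Gaussian noise (gain 1,
  SD 2) applied last.  2-D stacks place the axon along the centre row
  with a Gaussian transverse profile.

What the generator does *not* emulate: curved or drifting axons,
photobleaching, uneven labelling along a mitochondrion, focus drift,
mitochondria passing each other, and sub-resolution contact dyads.
Passing tests therefore demonstrate correctness of the measurement rules
and estimators under the stated imaging model, not robustness to every
artefact of real recordings.

## Problem sizes and numerical choices

The validation suite runs 50 noise-free axons (110 frames, ~5
mitochondria each) for exact event-calling checks; 500 mitochondria for
the fission-rate recovery (with the movie extended a few frames past the
10-min analysis window so the hazard is live for exactly 200 frame
intervals); ~250 fission events for the transport-probability recovery;
~400 completed runs for the switch-fraction recovery; and ~200 events
across 40 axons for the null calibration of the overlap statistic.
Recovered proportions are accepted inside exact central binomial 95 %
intervals around the configured values.  Event matching against ground
truth tolerates the few-frame lag between a true scission and the first
frame at which the separation criterion is met (up to 10 frames,
1.5 μm).  All tolerances (segmentation ± 1 pixel, fusion additivity
± 2 pixels, uniformity CV 0.15, overlap plateau factor 1.6) are stated at
their point of use in the code.
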