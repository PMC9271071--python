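# Methods

This note documents the models, conventions and design decisions behind the
package, in the spirit of a methods supplement: what each stage assumes, which
parameters matter, what the synthetic generator does and does not emulate,
and the numerical choices a maintainer would need to know.

## Conventions

All times are in seconds from session start; coordinates in pixels.  Analysis
bins are half-open 100 ms intervals [t, t + 0.1); relative bin 0 is the bin
containing the event time.  Trial indices are 1-based in time order; bin
indices are 0-based.  All randomness flows from integer seeds through
`numpy.random.default_rng`; the session generator splits one root seed into
per-stage seeds with `SeedSequence`, so identical (config, seed) pairs yield
byte-identical bundles.

## Behavioral inference

**Change-point engine.** Every change point in the package is the global
optimum of a single-split, two-segment, piecewise-constant mean fit: the
split minimising the total residual sum of squares, searched exhaustively
over splits leaving at least 2 elements per segment.  This matches the
single-change behavior of Matlab's `findchangepts`.  The reported index is
the first element of the post-change segment; the magnitude is the absolute
difference of segment means.  Ties break toward the earliest split, with a
small tolerance (1e−9 relative to the sequence's sum of squares) so that
floating-point noise in the prefix-sum evaluation cannot override a true
tie.  Constant sequences carry no change point.  Note the estimator's
intrinsic limits: on a Bernoulli(0.9)→Bernoulli(0.2) switch over 24+24
trials, even this exact optimum lands within ±1 trial of the true boundary
only ~80% of the time, because single-trial flips adjacent to the boundary
(e.g. two approaches right after the switch) legitimately move the optimal
split.

**Approach likelihood.** Snout position is resampled onto the 10 Hz bin grid
over [0, 12] s after CS+ onset (CS 4 s + access 8 s); velocity comes from
central differences of the resampled positions.  The four dimensions
(x, y, vx, vy) are z-scored jointly over all trials and bins — pixels and
pixels/second are incommensurable, so distances must not be unit-dominated.
Weights are normalised inverse distances with a regulariser ε = 1e−6 in
z-units, so an exact kinematic match receives near-total weight without a
division failure.  q_i(t) is a convex combination of the other trials'
binary approach statuses and is therefore bounded by them.

The inverse-distance kernel is heavy-tailed: many moderately distant trials
can outweigh a few near-identical ones.  In practice q_i(t) rises decisively
when the trial's kinematic state becomes *population-typical* of approach
trials — which requires approach movements to be stereotyped across trials.
This matters for what initiation recovery can and cannot show (see the
generator section below).

**Drinking.** Drink initiation is the first tracking sample during the access
window within 9 px of the cued sipper.  Surrogate approach/drink times for
event-less trials are drawn uniformly with replacement from the session's
real event times; real-event trials are never modified.

**Session phenotype.** Alcohol+quinine consumption is z-scored within strain
(sample SD); a compulsive-default session is reclassified non-compulsive when
z < −1.4 *and* the decrease from the preceding alcohol session exceeds 50%,
and a non-compulsive-default session is reclassified compulsive when z > +1.4
*and* the decrease is below 50%.

## Spike preprocessing

Counts are binned at 100 ms and smoothed per neuron with a Gaussian kernel
whose SD is one quarter of that neuron's mean inter-spike interval —
"adaptive" across neurons (rate-dependent bandwidth), constant over time for
a given neuron.  The kernel is truncated at ±4 SD and applied with
reflecting boundaries.  Reflection is the one boundary rule that satisfies
both requirements we impose on smoothing: constants pass through exactly
(the folded kernel has unit mass everywhere) and the total spike count is
conserved exactly (each spike's truncated mass folds back into the
recording).  Per-source renormalisation without padding conserves counts but
distorts constants at the edges; per-target renormalisation preserves
constants but leaks counts.  Units with fewer than two spikes (mean ISI
undefined) pass through unsmoothed and are flagged.

Alignment windows are inclusive relative-bin ranges: [−100, 200] for CS+ and
CS alignments (−10 s to +20 s), [−50, 20] for approach initiation, and
[−100, 100] for drinking.  Events whose window would leave the recording are
dropped (tensors stay rectangular, z-scoring stays unambiguous).  z-scoring
is per neuron over all (trial, bin) cells of each alignment separately —
the mean/SD are alignment-specific, matching the per-alignment definition of
the trial means; constant-rate units map to zero and are flagged.  The eight
trial-type means are concatenated in the fixed order
[a⁺ a⁻ b⁺ b⁻ c⁺ c⁻ d⁺ d⁻]; with default windows the profile is
2·(301+301+71+201) = 1748 bins, and the emitted segment map covers every bin
exactly once.

## Subsampled PCA, stability and separation

Each iteration draws, without replacement, the same number of neurons from
every group (defaults: 500 iterations × 200 neurons per group) and runs PCA
with neurons as variables and the 1748 profile bins as observations
(per-neuron centering over bins; SVD).  Stored score traces are the raw
projections X·f, so that projecting a whole-sample group through an
iteration's coefficients reproduces that iteration's scores exactly; the
centered scores (used for the reconstruction identity) differ only by a
constant per PC, which affects neither variance ratios nor sign alignment.

PCs are matched across iterations by explained-variance rank — the only
index available — and sign-aligned by iteratively flipping iterations whose
score trace anti-correlates with the cross-iteration mean (≤10 passes; an
exactly mirrored pair cancels the mean, in which case the first iteration
seeds the reference).  The stability ratio is the variance over time of the
iteration-mean trace divided by the variance of deviations over (bins ×
iterations); ratio > 1 is stable.  A zero deviation variance (identical
traces every iteration) reports an infinite sentinel and counts as stable.

Two structural caveats of rank-matched stability selection are worth
recording. First, subsampling must be substantially smaller than the
population: if each iteration shares most units with every other, even
pure-noise PCs correlate across iterations and their ratios drift above 1.
Second, latent signals of nearly equal variance swap ranks across
iterations, which washes out the rank-averaged trace for *any*
implementation; stability selection presupposes a reasonably separated
spectrum.

Group trajectories are iteration means of E_{j,k}(t) = Σ_{i∈G_k} f_{i,j,k}
A_i(t) over the group's selected units; separation between two trial types
is the per-bin Euclidean distance across stable PCs between the two segment
trajectories.  Default 20-bin epochs: seeking −2.5..−0.6 s before CS+
(before the cue, clear of it); cue onset, paired windows on the CS+ trace
(pre-CS −2.4..−0.5 s vs CS 0..1.9 s); CS+/− discrimination 2.0..3.9 s of the
CS (past the shared onset transient); approach −3.0..−1.1 s before
initiation (clear of movement onset); drink 0..1.9 s after drink time.  The
exact seeking and CS+/− epoch bounds are configurable and recorded in output
metadata.

**Controls.** The shuffle null permutes the trial-type labels feeding the
epoch's comparison within each session and recomputes the entire stack; the
identity permutation reproduces the observed value exactly.  Note the
statistics of this control: under a true null the observed value is
exchangeable with its shuffles, so it falls inside the central 90% of a
100-shuffle null with probability 0.90 per dataset — no more.  A criterion
demanding that coverage in ≥90% of 20 datasets is therefore passed by a
perfectly calibrated pipeline only ~68% of the time; the meaningful
calibration statements are "coverage ≈ 90%" and "a strongly planted signal
exceeds the null's 95th percentile".  Leave-one-out reruns the analysis with
each animal's units removed, skipping holdouts that empty a group or leave
it below the subsample size.  The firing-rate-change control compares the
mean absolute per-unit rate change between the trials adjacent to the
session change point against re-centerings jittered by up to ±2 trials.

## Waveform classification

The largest-amplitude mean waveform is affinely rescaled so the trough
(maximum hyperpolarisation) is −1 and the post-trough depolarisation peak
+1.  t50 and t95 are the first times, measured from the trough, at which the
rise crosses the 50% and 95% levels of that range (values 0.0 and 0.9), with
linear interpolation between samples; a rise that never reaches the 95%
level marks the unit an outlier.  The published workflow clustered these
delays manually; reproducibility requires an algorithmic stand-in, so units
are partitioned by a seeded 2-means on the standardised (t50, t95) plane,
the faster-depolarising cluster (smaller mean t95) is labelled putative
inhibitory, and points farther than 4 cluster SDs from their centroid along
either standardised feature are outliers.  Because a single extreme point
can hijack a 2-means centroid, outlier removal and re-clustering iterate (up
to 3 passes).  Classification operates on normalised shapes and is invariant
to amplitude scaling.  Labels are explicitly *putative*: several interneuron
classes are known to be waveform-indistinguishable from pyramidal cells.

## The synthetic session generator

The generator emulates the study conditions: 48 CS+ and 48 CS− trials;
intertrial intervals drawn from {20, 28, 36, 44, 56, 68, 96, 120} s (defined
sipper-retraction to next CS+ onset); CS− trials strictly inside intertrial
gaps, at least 3 s from CS+ trial boundaries; consecutive trials differing
in CS type with probability ≈ 0.6; approach per CS+ trial Bernoulli(0.9)
before the planted change-point trial and Bernoulli(0.2) at/after (CS−
approaches at the same state-dependent rates, since CS− approaches carry no
penalty); correct side with probability 0.9; drinking on 95.08% of correct
approaches.

**Trial-type sequence.** A naive sequential draw with P(switch) = 0.6
under-alternates once one CS type runs out, so the sequence is drawn from
the Markov law *conditioned* on exact trial counts — and on CS− runs no
longer than the largest intertrial interval can hold — by dynamic
programming over (remaining counts, current type, run length).  Empirical
alternation is 0.605, within the task's "approximately 60%".  Intertrial
intervals are drawn uniformly from the members of the interval set that can
hold the gap's CS− count; the schedule errors only when no member can.

**Tracking.** Between trials the snout wanders (low-pass-filtered AR(1)
around the arena centre, kept 40 px clear of the sippers).  Approach
movements are stereotyped: a launch latency of 0.5 + Gamma(100, 0.02) s
(mean 2.5 s, SD 0.2 s, clipped into [0.5, cs+2]), a 0.1 s dart onto the
chamber midline, then a constant-speed run (450 px/s) along the midline to
the sipper, a dwell (through the access period on correct trials; a few
seconds otherwise, always ending before the next CS+ trial), and a blend
back to the wander.  Gaussian position noise (SD 3 px) is measurement noise
added everywhere.  The stereotypy is deliberate: the approach-likelihood
kernel identifies initiation by comparing kinematic states at matched
relative times, so departure is only localisable when approach movements
resemble each other trial-to-trial.  With these kinematics the detected
initiation recovers the planted departure with median error ≈ 0.25 s; with
dispersed latencies or idiosyncratic straight-line paths the same kernel
localises sipper *arrival* instead, a structural property of the method, not
an implementation artifact.  Real pose data are messier in ways the
generator does not emulate (tracking dropouts, rearing, grooming, multi-goal
trajectories), so passing recovery tests demonstrate correctness of the
machinery under identifiable conditions, not field performance on arbitrary
video.

**Spikes.** Each unit fires as an inhomogeneous Poisson process at 1 ms
resolution with a log-linear rate,

    λ_i(t) = b_i · exp( Σ_s L_is · gain_s · g_s(t) ),

where the four channels g_s are: a pre-CS seeking offset (1 over the 10 s
before CS+ onset, pre-change-point trials only), a cue response (alpha
transient, τ = 0.4 s, plus a 0.5 plateau sustained while the 4 s light is
on — the sustained part is what makes late-CS discrimination epochs
meaningful), a 3 s linear ramp into approach initiation with a 0.5 s decay,
and a drink transient (alpha kernel, τ = 0.5 s, 3 s support).  The
exponential link guarantees positivity; rates above a hard cap (200 Hz) are
a configuration error.  Loadings L_is are gamma distributed (mean 0.3, CV
0.35) with a bounded tail (mean·(1+4·CV)) so the worst-case overlap of
channels stays below the cap across the supported gain range.  Baselines are
4 Hz for putative excitatory units and 2.5× that for the putative
inhibitory fraction (15%).  Sampling is exact superposition: a homogeneous
baseline process plus Poisson counts of the nonnegative excess rate on the
signal-active bins, so the expected count equals ∫λ dt exactly.  Waveforms
come from two-Gaussian templates (narrow-fast vs broad-slow depolarisation)
plus noise.  Ground truth — change-point trial, per-trial initiation and
drink times, per-unit loadings, classes and expected counts — is emitted on
a separate channel that no analysis function reads.

## Problem sizes

The test-suite and acceptance-script runs use reduced but structurally
complete problems: 24 CS+ / 24 CS− sessions with short intertrial intervals
(20–44 s), 40–200 neurons, and subsample designs of 10–100 iterations with
25–50 neurons per group; the full default design (48+48 trials, 500 × 200)
is exercised where the quantity under test is the design itself.  These
sizes were chosen so the entire validation remains a desk-scale computation
while preserving every structural property the full configuration has.

## Known limitations

* Rank-matched stability selection degrades when latent signals have nearly
  equal variance or when subsamples overlap heavily (see above).
* Approach-initiation detection inherits the inverse-distance kernel's bias
  toward population-typical states; on weakly stereotyped behavior it dates
  arrival, not departure.
* The waveform classifier is a reproducible stand-in for manual clustering;
  its outlier threshold (4 SD) and the 2-means seed are recorded in outputs
  but were not tuned to any real dataset.
* The generator plants rate modulations with a single global timescale per
  channel; it does not emulate bursting, adaptation, correlated noise across
  units, or electrode drift.
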