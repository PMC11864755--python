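# Methods

`pingmap` implements, end to end, the analysis by which a hidden spatial
attentional priority map is reconstructed from multichannel alpha-band
oscillations: an inverted encoding model (IEM) over eight circular display
locations applied to evoked or total alpha power, with partitioned
training/testing, cross-session generalization, channel-tuning-function
(CTF) slope statistics, a distance-gradient regression around a
high-probability distractor location (HPL), and the accompanying behavioral
analyses. Because the package's purpose is the *pipeline*, not a specific
dataset, it ships a synthetic-data generator that produces experiments with
this exact statistical structure and full ground truth, so every stage can
be validated by parameter recovery.

## The simulated experiment

The generator emulates a two-phase design. In the **training phase**
(localizer; 10 blocks x 80 trials) participants only memorize the angular
location of a cue drawn from 8 bins at 45 deg spacing, with uniform angular
jitter on [-22.5, 22.5) deg added to the bin center so that all angles
occur. In the **test phase** (10 blocks x 92 trials) an
additional-singleton search task is embedded in the memory maintenance
interval: a color-singleton distractor appears on 74% of trials, at one
fixed high-probability location on 65% of those and at each of the seven
low-probability locations on 5%; the target never co-occurs with the
distractor; 13% of trials replace the memory cue with a neutral fixation
(no-memory trials). Conditions are sampled i.i.d. per trial rather than
counter-balanced per block, matching the probabilistic description of the
design; composition checks are therefore stochastic and are asserted
within 4 binomial standard errors.

Behavioral outcomes are additive: RT = base (1000 ms) + capture cost when
a distractor is present (+50 ms) + a delta depending on the distractor's
circular bin distance from the HPL (defaults -50, -25, 0, 0, 0 ms for
distances 0-4, i.e. suppression strongest at the HPL with a spatial
gradient) + a cost when the *target* occupies the HPL (+60 ms) + a
repetition benefit when the distractor location repeats (-40 ms), plus
Gaussian noise (SD 150 ms, negative draws resampled). Accuracy is
Bernoulli (base 90%) with small per-distance deltas. Recall error is
wrapped-normal, SD 6 deg in the training phase and 12 deg in the test
phase, emulating the degradation caused by the embedded search task
without reproducing any dataset-specific value.

Note one structural property of this design: because target and distractor
never share a location, the target-at-HPL contrast is partially confounded
with the distractor-location deltas (trials with the target at the HPL can
never enjoy the distractor-at-HPL benefit). The recovery tests therefore
plant each behavioral effect in isolation when asserting that the
corresponding contrast estimates it.

## Forward model for epochs

Epochs are trials x electrodes x samples (default 64 electrodes in the
standard 10-10 layout, 512 Hz). Eight spatial channels — neuronal
populations tuned to the eight display angles — project to electrodes
through a mixing matrix: each channel's topography is a Gaussian bump
(width 5 cm) over posterior scalp centered at a point on a posterior ring
at the channel's angle, plus a small seeded random component that breaks
symmetry; columns are normalized and the matrix is verified to have full
column rank so the IEM inverse is well posed. The true spatial profile of
location-tuned alpha topographies is not identifiable from published
material, so this mixing matrix is an explicit modeling choice of the
generator, not an estimate.

Per trial, channel activations are the basis responses (below) at the
exact jittered cue angle. The electrode signal is `mixing @ activations`
carried by a 10 Hz alpha oscillation with two components:

- an **evoked** component with a fixed carrier phase across trials
  (phase-locked to stimulus onset), with a transient envelope (50 ms
  half-cosine rise, 150 ms plateau, 300 ms fall) at memory-cue onset and
  again at placeholder ("ping") onset;
- an **induced** component with a uniform random carrier phase per trial
  and a sustained envelope from cue onset to the end of the epoch
  (maintained activity).

The ping-evoked envelope is multiplied by a configurable gain that depends
on the cue's circular bin distance (0-4) from the HPL — this is how a
priority-map gradient is planted. No-memory trials contain noise only.
Noise is 1/f-power ("pink") noise with random phases (amplitude 4, in units
of the unit-norm mixing columns) plus white noise (amplitude 1); per-trial,
per-electrode SNR is therefore well below one. The noise level was
calibrated once so that single-subject CTF recovery succeeds at roughly
800 trials, the scale of a full session, and is part of the generator's
defaults rather than a per-experiment dial.

What the generator does *not* emulate: volume-conducted correlated noise,
saccade dynamics or realistic ocular/muscle generators (artifacts are
injected as parametric bursts, HEOG steps and gaze excursions), eye-tracker
sample streams, head-model lead fields, or the recall mouse response.
Passing recovery tests therefore show that the *analysis* is correct and
well calibrated under its own assumptions, not that real EEG satisfies
those assumptions.

## Preprocessing

Muscle artifacts: the signal is band-passed 110-140 Hz (fourth-order
Butterworth, zero-phase), the Hilbert envelope is z-scored per electrode
across the whole recording, and the electrode-summed z trace is compared
to a subject-specific threshold inside the windows of interest. The
functional form of a "subject-specific" threshold is a genuinely open
design choice; here it is median + c * (1.4826 * MAD) with c = 4, a robust analogue of
mean + c * SD chosen so that contaminated samples cannot inflate the
threshold itself. Flagged epochs are not dropped immediately: up to five
electrodes contributing most to the accumulated z within the artifact
period are interpolated one by one, re-testing after each, and only epochs
still above threshold are dropped. With default burst amplitudes the
procedure reaches sensitivity 1.0 at false-positive rate 0 on the
generator's truth masks; single-electrode bursts are repaired, bursts on
eight simultaneous electrodes are dropped.

Interpolation uses the inverse-distance-weighted mean of the four nearest
non-flagged electrodes instead of spherical splines. Interpolation quality
is not a scientific target of this package; the contract that matters —
the artifact is removed and the result tracks the local topography — is
testable either way, and the simpler scheme has no free smoothing
parameters. The deviation from spline interpolation is deliberate and
documented here so results are not mistaken for spline-interpolated ones.

Eye movements: epochs are rejected when gaze eccentricity exceeds 1.2
visual degrees anywhere in the window of interest; without gaze data, a
sliding-window step detector on the HEOG channel (200 ms window, 10 ms
step) rejects epochs with a step exceeding 15 uV between the means of the
window's two halves. Independent-component blink removal is out of scope;
the generator does not produce blinks.

## Spectral analysis

Alpha-band analytic signals come from a fifth-order Butterworth band-pass
at 8-13 Hz applied forward-backward (zero phase) followed by a Hilbert
transform. The default band is 8-13 Hz; the narrower nominal alpha band
(8-12 Hz) is equally valid and both are configurable. Zero-phase
filtering is essential here because CTF latencies are interpreted in time;
its cost is symmetric temporal smearing — a transient bleeds roughly
100-200 ms in both directions at this bandwidth, which is why analysis
windows leave a gap around event onsets and why a "baseline" ending
immediately before an onset would be contaminated by design.

**Evoked power** is the squared magnitude of the across-trial mean
analytic signal of a trial group; only phase-locked activity survives the
complex mean. **Total power** averages per-trial squared magnitudes and
captures all activity. Both are computed per partition set x cue bin,
*after* partitioning, and recomputed in every partition iteration. Power is
smoothed with an 8-sample moving average (15.62 ms at 512 Hz), then
optionally reduced to 16 principal components. The PCA rotation is fitted
on the training observations only, pooled over time samples, and applied
unchanged to the test block; fitting before versus after partitioning is a
genuinely open ordering question, and this choice avoids any train/test
leakage. The rotation is
uncentered by default: power carries a large common offset that is itself
informative, and an uncentered orthonormal rotation leaves the
encoding-model solution exactly invariant when all components are
retained (verified to 1e-12 in the tests).

## Inverted encoding model

Each of k = 8 spatial channels has the half-sinusoid response profile
R(theta) = sin(0.5 theta)^7, circularly shifted so the peaks sit at 0, 45,
..., 315 deg; equivalently the response at angular distance d from a
channel's center is cos(d/2)^7. Training solves the GLM B1 = W C1 for the
electrode(or component)-by-channel weight matrix by least squares per time
sample, where C1 holds the basis responses at each training observation's
bin center (bin centers, not jittered angles, are the design unit; exact
angles are available via configuration). Testing inverts the model,
solving W C2 = B2 for the channel responses, again per time sample, and
requires W to have full column rank — with m features > k channels the
normal equations are well conditioned, which is why the default keeps 16
components for 8 channels; at m = k the inversion is exactly determined
and can amplify noise at low-power samples.

Estimated responses are circularly re-centered so the cued channel sits at
offset 0, and aggregated three ways: per physical location bin, grouped by
the bin's circular distance (0-4) from the HPL, and grand-averaged over
bins.

Training/testing uses disjoint trial sets with equated per-bin counts:
each bin is randomly subsampled to floor(min_count / n_sets) * n_sets
trials (the discard rule when counts are unequal) and dealt equally to the
sets. Within-session mode partitions the localizer into three sets (two
train, one test); cross-session mode splits the localizer into two
training sets and uses the entire test phase as the test set, with
training and test time axes required to match exactly. Because one random
partition is noisy, the whole partition -> power -> train -> invert ->
re-center loop is repeated (100 iterations at full scale) with seeds
derived from a master seed, and CTFs are averaged across iterations.

## Statistics

CTF slope: the two symmetric offsets at each angular distance are folded
(averaged), giving five points at distances 0-4; a least-squares line is
fitted and its coefficient is sign-flipped so that positive slope =
spatial selectivity. Folding halves the variance and is standard for this
estimator; the ideal basis profile (1, 0.5745, 0.0884, 0.0012, 0) has
slope 0.2573. The estimator is linear in the CTF and maps a flat CTF to
exactly 0.

Group inference uses a cluster-based one-sample sign-flip permutation
test: one-sample t values per time sample, clusters of contiguous samples
with |t| above a threshold and consistent sign, cluster mass = summed t,
and a null distribution of the maximum |mass| over 1024 random
per-subject sign flips. Each cluster's p-value is
(1 + #{null >= |mass|}) / (1 + n_perm); the +1 correction avoids p = 0.
The cluster-forming threshold defaults to the two-tailed t critical value
at alpha = 0.05 with n_subjects - 1 df; because no single convention
dominates, the threshold is exposed in the configuration. Family-wise
type-I error is verified by simulation (200 null group datasets).

The distance gradient regresses CTF slope on distance 0-4 per subject and
per time sample and submits the per-subject coefficients to the same
cluster test; a negative coefficient means selectivity decreasing away
from the HPL. The regression could be fitted at the subject or the group
level; fitting per subject keeps the permutation test exact under subject
exchangeability.

Behavior: RTs drop incorrect responses and RTs < 200 ms first, then a
per-subject +/-2.5 SD cut computed on the condition-collapsed distribution
of what remains (the < 200 ms filter is applied before the SD is computed;
the opposite order would let anticipations inflate the SD). Trials count as low-probability only when *neither* the distractor
nor the target occupies the HPL, so the target-at-HPL cost cannot
contaminate the LPL baseline. Distance groups 1-4 inherit the same
exclusion. Repetition compares consecutive distractor-present pairs with
equal versus different distractor bins. Planned paired t tests (Cohen's d
on the paired differences; t = 0, p = 1 when all differences vanish), a
one-way repeated-measures ANOVA over distances 1-4 with
Greenhouse-Geisser correction and partial eta squared, and
Holm-Bonferroni-corrected pairwise follow-ups are computed through
pingouin/statsmodels. Bayes factors are out of scope.

## Problem sizes and numerical choices

The full-scale configuration (24 subjects, 800 + 920 trials, 64
electrodes, 100 iterations, 1024 permutations) is available but the
default desk-scale pipeline and the recovery studies use reduced sizes
chosen once: 12 subjects x 200 trials per phase, 32 electrodes, 8
iterations and 512 permutations, with ping-locked epochs (-0.35 to 0.55 s
plus 0.2 s filter padding). At these sizes a full recovery study completes
in under half a minute per run on one core while group-level cluster and
gradient tests remain decisively powered (permutation p ~ 0.002-0.03).
Recovery studies that isolate the ping revival set the induced amplitude
to zero so that phase-locked tuning exists only where planted.

Other numerical conventions: smoothing uses replicated edges (a constant
series is unchanged); power non-negativity is asserted with a 1e-12
slack; rank checks on the inversion use the eigenvalues of W'W with a
relative 1e-20 floor; all randomness flows through numpy Generators seeded
from explicit integers, and a `RunConfig` derives per-stage seeds from one
master seed via CRC-tagged `SeedSequence`s, so identical configurations
produce bit-identical reports.

## Known limitations

- Electrode power is quadratic in the coherent channel sum, so the linear
  IEM recovers a sharpened, amplitude-distorted version of the planted
  tuning profile; slope-based inference (sign, localization in time,
  monotone gradients) is unaffected, and exact-recovery oracles are
  therefore stated at the envelope/model-consistent level.
- The generator's artifacts are parametric stand-ins; detection thresholds
  calibrated on them (sensitivity >= 0.9, FPR <= 0.05) do not transfer
  verbatim to real recordings.
- Cross-session mode assumes the two sessions share electrode geometry and
  noise statistics — true here by construction, an empirical question on
  real data.
- No-memory trials are generated (and carry noise-only epochs) but no
  priority decoding is attempted on them.
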