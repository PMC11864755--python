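# pingmap

Reconstructing a hidden spatial attentional priority map from multichannel
alpha-band oscillations — an inverted encoding model (IEM) pipeline for
"pinging" experiments, exercised end to end on synthetic EEG with known
ground truth.

## The problem

When people learn that a salient distractor usually appears at one display
location (the high-probability location, HPL), search improves there —
but is the location suppressed *proactively*, before attention moves, or
*reactively*, after it is first selected? One way to ask the question is
to hold a spatial memory in mind, flash a neutral high-contrast
"placeholder" display (a ping) before search, and read the hidden priority
map off the evoked response: the ping revives location-tuned alpha-band
activity whose strength can be compared across distances from the HPL.

`pingmap` implements the full analysis chain for that design, for
methodologists and students who want a tested, reusable, simulation-backed
implementation rather than a one-off analysis script:

- **synthetic data** (`pingmap.simulate`): a two-phase experiment
  (memory-only localizer; test phase with an embedded additional-singleton
  search task: distractor on 74% of trials, 65% of those at the HPL, 5%
  at each other location, 13% no-memory trials), and a linear forward
  model producing multichannel epochs with location-tuned alpha whose
  phase-locked (evoked) and random-phase (induced) components, ping-evoked
  revival, distance gradient, noise and artifacts are all controllable and
  recorded as ground truth;
- **preprocessing** (`pingmap.preprocess`): z-score muscle-artifact
  detection (110-140 Hz) with iterative up-to-five-electrode
  interpolation before dropping, and eye-movement rejection by gaze
  threshold (1.2 deg) or HEOG step detection (200 ms / 10 ms / 15 uV);
- **spectral analysis** (`pingmap.spectral`): fifth-order Butterworth
  8-13 Hz zero-phase filtering, Hilbert analytic signals, evoked vs total
  power, 8-sample smoothing, train-fitted PCA;
- **encoding model** (`pingmap.iem`, `pingmap.partitioning`): half-sinusoid
  basis R(theta) = sin(0.5 theta)^7 over 8 channels, least-squares
  training B1 = W C1, inversion W C2 = B2, circular re-centering into
  channel tuning functions (CTFs), three-set partitioning with per-bin
  trial equating and 100-iteration averaging, within-session and
  cross-session (train on localizer, test on test phase) modes;
- **statistics** (`pingmap.ctf_stats`, `pingmap.behavior`): folded CTF
  slopes, cluster-based sign-flip permutation tests (1024 permutations),
  the slope-vs-distance gradient regression around the HPL, RT trimming
  and condition contrasts with paired t tests and a Greenhouse-Geisser
  corrected repeated-measures ANOVA.

The model/results interface follows the statsmodels idiom:
`SpatialEncodingModel(...).fit()` returns a results object with the
iteration-averaged CTFs and slope time courses; `GroupResults` stacks
subjects and exposes `cluster_test()`, `gradient_test()` and `summary()`.

## Worked example

Simulate a small cross-session study in which the ping-evoked tuning
amplitude decreases with distance from the HPL (gradient multipliers
2.0, 1.5, 1.0, 0.75, 0.5 for distances 0-4), fit the encoding model per
subject on evoked alpha power, and test the group:

```python
from pingmap import (BehaviorEffects, DesignConfig, EpochTiming, ForwardModel,
                     GroupResults, SpatialEncodingModel)
from pingmap.simulate import build_mixing, simulate_subject

design = DesignConfig()
fwd = ForwardModel(n_electrodes=32, induced_amp=0.0, ping_amp=1.2,
                   gradient=(2.0, 1.5, 1.0, 0.75, 0.5))
timing = EpochTiming.ping_locked(tmin=-0.35, tmax=0.55, pad=0.2)
mixing = build_mixing(fwd)

results = []
for s in range(8):
    trials, ep_train, ep_test = simulate_subject(
        design, BehaviorEffects(), fwd, timing, subject=s, seed=0,
        n_trials_train=200, n_trials_test=200, mixing=mixing)
    model = SpatialEncodingModel.from_epochs(
        trials, ep_train, ep_test, mode="cross", kind="evoked",
        hpl_bin=design.hpl_bin, n_components=16)
    results.append(model.fit(n_iter=8, seed=s))

group = GroupResults(results)
print(group.summary(windows={"baseline": (-0.35, -0.05),
                             "ping": (0.0, 0.5)}, n_perm=512))
grad = group.gradient_test(window=(0.0, 0.5), n_perm=512)
print("gradient cluster p-values:", grad.cluster.pvals)
print("gradient cluster masses:  ", grad.cluster.masses.round(1))
```

Output (about 15 seconds on one core):

```text
Spatial encoding group results (8 subjects, evoked power, mode=cross)
  baseline: mean CTF slope -0.0003; 0 significant cluster(s)
  ping: mean CTF slope 0.0889; 1 significant cluster(s), smallest p = 0.01365
gradient cluster p-values: [0.0214425]
gradient cluster masses:   [-210.6]
```

Reading it: in the pre-ping baseline the mean CTF slope is near zero and
no cluster survives the permutation test — the memory location is not
decodable from evoked power before the ping. After ping onset the slope
is clearly positive with a significant cluster (the ping revives the
location-tuned response), and the slope-vs-distance regression yields a
significant *negative*-mass cluster: tuning is strongest for memory cues
at the HPL and falls off with distance, recovering the planted gradient's
sign.

A YAML-configured end-to-end run (simulate -> preprocess -> spectral ->
encode -> stats -> behavior -> JSON report) is available both as
`pingmap.pipeline.run_pipeline(RunConfig(...))` and from the shell:

```bash
pingmap run-all --config config.yaml --seed 1 --out results/
pingmap simulate --seed 1 --out sim/      # single-subject stage commands:
pingmap preprocess --epochs sim/epochs_train.h5 --out clean.h5 --report rep.json
pingmap encode --trials sim/trials.csv --train-epochs clean.h5 --iters 100 --out ctf.h5
pingmap stats --ctf ctf1.h5 --ctf ctf2.h5 --test gradient --out stats.json
pingmap behavior --trials trials.csv --hpl 4 --out behavior.json
```

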