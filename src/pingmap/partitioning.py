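"""Trial partitioning and the iterative CTF-averaging loop.

Within-session analysis (the localizer): trials are randomly partitioned
into three independent sets with equated per-bin counts; two sets train the
encoding model, the third is the test set.  Cross-session analysis: the
localizer is split into two training sets and the entire test phase serves
as the test set, with training and test time samples strictly aligned.
Because a single random partition is noisy, the partition -> power ->
train -> invert -> re-center loop is repeated (100 iterations in the full
analysis) and the resulting CTFs are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iem import (ChannelResponses, invert_channels, make_basis,
                  predicted_responses, recenter_ctf, train_weights)
from .spectral import (AnalyticEpochs, evoked_power, pca_reduce, smooth_power,
                       total_power)

__all__ = ["PartitionPlan", "partition_equate", "run_iem_iterations"]


@dataclass
class PartitionPlan:
    """Assignment of trial positions to disjoint, per-bin-equated sets.

    ``train_sets`` maps set id -> {bin -> array of trial positions};
    ``test_set`` is the same per-bin mapping for the held-out data.  In
    'within' mode the test set is one of the three partitions; in 'cross'
    mode it is the whole test phase.
    """

    mode: str
    train_sets: dict
    test_set: dict
    seed: int
    n_per_bin: int

    def all_train_positions(self) -> np.ndarray:
        return np.concatenate([idx for s in self.train_sets.values()
                               for idx in s.values()])

    def all_test_positions(self) -> np.ndarray:
        return np.concatenate(list(self.test_set.values()))


def _equated_split(bins: np.ndarray, n_sets: int, rng: np.random.Generator,
                   n_bins: int = 8) -> tuple[dict, int]:
    """Subsample each bin to the same divisible-by-n_sets count and split."""
    positions = {b: np.flatnonzero(bins == b) for b in range(n_bins)}
    counts = {b: len(p) for b, p in positions.items()}
    short = [b for b, c in counts.items() if c < n_sets]
    if short:
        raise ValueError(
            f"bin(s) {short} have fewer than {n_sets} usable trials "
            f"(counts: {counts})")
    keep = (min(counts.values()) // n_sets) * n_sets
    sets = {s: {} for s in range(n_sets)}
    for b, pos in positions.items():
        chosen = rng.permutation(pos)[:keep]
        for s in range(n_sets):
            sets[s][b] = np.sort(chosen[s::n_sets])
    return sets, keep // n_sets


def partition_equate(trials: pd.DataFrame, mode: str = "within",
                     seed: int = 0, n_sets: int = 3) -> PartitionPlan:
    """Random per-bin-equated partition of a trial table.

    Trials without a cue bin (no-memory trials) are ignored.  Each bin is
    randomly subsampled to ``floor(min_count / n_sets) * n_sets`` trials
    (the discard rule when counts are not divisible), then dealt equally to
    the sets.  ``mode='within'`` partitions the training phase into
    ``n_sets`` sets, the last of which is the test set; ``mode='cross'``
    splits the training phase into two training sets and uses every usable
    test-phase trial as the test set.
    """
    rng = np.random.default_rng(seed)
    usable = trials[trials["cue_bin"].notna()]
    train_rows = usable[usable["phase"] == "training"]
    positions_of = lambda rows: rows["cue_bin"].to_numpy(dtype=int)

    if mode == "within":
        bins = positions_of(train_rows)
        local = np.flatnonzero((trials["phase"] == "training").to_numpy()
                               & trials["cue_bin"].notna().to_numpy())
        sets, n_per = _equated_split(bins, n_sets, rng)
        sets = {s: {b: local[idx] for b, idx in d.items()} for s, d in sets.items()}
        test_set = sets.pop(n_sets - 1)
        return PartitionPlan("within", sets, test_set, seed, n_per)
    if mode == "cross":
        bins = positions_of(train_rows)
        local = np.flatnonzero((trials["phase"] == "training").to_numpy()
                               & trials["cue_bin"].notna().to_numpy())
        sets, n_per = _equated_split(bins, 2, rng)
        sets = {s: {b: local[idx] for b, idx in d.items()} for s, d in sets.items()}
        test_local = np.flatnonzero((trials["phase"] == "test").to_numpy()
                                    & trials["cue_bin"].notna().to_numpy())
        test_bins = trials["cue_bin"].to_numpy(dtype=float)[test_local]
        test_set = {b: test_local[test_bins == b] for b in range(8)}
        empty = [b for b, p in test_set.items() if len(p) == 0]
        if empty:
            raise ValueError(f"test-phase bin(s) {empty} have no usable trials")
        return PartitionPlan("cross", sets, test_set, seed, n_per)
    raise ValueError(f"unknown mode {mode!r}")


def _position_lookup(analytic: AnalyticEpochs) -> dict:
    return {int(t): i for i, t in enumerate(analytic.trial_index)}


def run_iem_iterations(trials: pd.DataFrame, analytic_train: AnalyticEpochs,
                       analytic_test: AnalyticEpochs | None = None, *,
                       mode: str = "within", kind: str = "evoked",
                       n_iter: int = 100, seed: int = 0,
                       hpl_bin: int | None = None, smooth_window: int = 8,
                       n_components: int | None = 16,
                       basis=None) -> ChannelResponses:
    """Iteration-averaged CTFs from repeated random partitions.

    For each iteration: partition trials, compute per-set x per-bin power
    (evoked or total) from the analytic signals, smooth, optionally reduce
    with train-fitted PCA, estimate weights on the training observations,
    invert on the held-out observations, and re-center on the cued channel.
    CTFs are averaged across iterations.  In 'cross' mode ``analytic_test``
    holds the test-phase epochs; its time axis must exactly match the
    training epochs (strict alignment of time samples).

    Trial tables are matched to epochs through ``trial_index`` /
    ``trials.index``, so preprocessing may have dropped epochs beforehand.
    """
    if basis is None:
        basis = make_basis()
    power_fn = {"evoked": evoked_power, "total": total_power}[kind]
    if mode == "cross":
        if analytic_test is None:
            raise ValueError("cross mode requires analytic_test")
        if (analytic_train.times.size != analytic_test.times.size
                or not np.allclose(analytic_train.times, analytic_test.times)):
            raise ValueError("training and test time samples are not aligned")
    test_analytic = analytic_test if mode == "cross" else analytic_train
    lut_train = _position_lookup(analytic_train)
    lut_test = _position_lookup(test_analytic)
    # restrict the table to trials that survived preprocessing
    present = trials.index.to_series().astype(int)
    keep = present.map(lambda t: (t in lut_train) or (t in lut_test)).to_numpy()
    trials = trials[keep]

    master = np.random.SeedSequence(seed)
    iter_seeds = [int(s % (2**31)) for s in master.generate_state(n_iter)]
    ctf_sum = None
    cue_bins_ref = None
    for it, it_seed in enumerate(iter_seeds):
        try:
            plan = partition_equate(trials, mode=mode, seed=it_seed)
            train_groups = {}
            for s, perbin in plan.train_sets.items():
                for b, rows in perbin.items():
                    tidx = trials.index.to_numpy()[rows]
                    train_groups[(s, b)] = [lut_train[int(t)] for t in tidx]
            test_groups = {}
            for b, rows in plan.test_set.items():
                tidx = trials.index.to_numpy()[rows]
                test_groups[("test", b)] = [lut_test[int(t)] for t in tidx]

            B1 = smooth_power(power_fn(analytic_train, train_groups), smooth_window)
            B2 = smooth_power(power_fn(test_analytic, test_groups), smooth_window)
            if n_components is not None:
                B1, B2 = pca_reduce(B1, B2, k=n_components)
            centers = basis.centers
            C1 = predicted_responses(centers[B1.obs["cue_bin"].to_numpy(dtype=int)],
                                     basis)
            W = train_weights(B1.as_b_matrix(), C1)
            C2 = invert_channels(W, B2.as_b_matrix())
            cue_bins = B2.obs["cue_bin"].to_numpy(dtype=int)
            res = recenter_ctf(C2, cue_bins, times=analytic_train.times,
                               hpl_bin=hpl_bin)
        except Exception as err:
            raise RuntimeError(f"IEM iteration {it} failed: {err}") from err
        if ctf_sum is None:
            ctf_sum = res.ctf
            cue_bins_ref = cue_bins
        else:
            if not np.array_equal(cue_bins, cue_bins_ref):
                raise RuntimeError("observation ordering changed across iterations")
            ctf_sum = ctf_sum + res.ctf
    return ChannelResponses(ctf=ctf_sum / n_iter, cue_bins=cue_bins_ref,
                            times=analytic_train.times, hpl_bin=hpl_bin)
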