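"""Config-driven end-to-end run: simulate -> preprocess -> spectral ->
encode -> stats -> behavior -> report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import condition_summary, stats_tests
from .config import RunConfig
from .containers import write_trials
from .model import GroupResults, SpatialEncodingModel
from .preprocess import detect_muscle_artifacts, reject_eye
from .simulate import build_mixing, simulate_subject

__all__ = ["run_pipeline", "analysis_windows"]


def analysis_windows(timing) -> dict:
    """Named analysis windows implied by the event timing.

    'baseline' precedes the first event; 'cue' spans cue onset up to the
    ping (or the window end); 'ping' spans ping onset to the window end.
    """
    first = min(x for x in (timing.cue_onset, timing.ping_onset)
                if x is not None)
    windows = {"baseline": (timing.tmin, first - 0.02)}
    if timing.cue_onset is not None:
        end = timing.ping_onset if timing.ping_onset is not None else timing.tmax
        windows["cue"] = (timing.cue_onset, end)
    if timing.ping_onset is not None:
        windows["ping"] = (timing.ping_onset, timing.tmax)
    return windows


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json())
    return obj


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None,
                 preprocess: bool = True) -> dict:
    """Execute the full analysis on a freshly simulated experiment.

    Simulates ``cfg.n_subjects`` subjects, optionally runs artifact and
    eye-movement rejection, fits the encoding model per subject, runs the
    group cluster and gradient tests in the timing-derived windows, runs
    the behavioral analysis, and returns (and optionally writes) a JSON
    report with a provenance block.
    """
    cfg.validate()
    mixing = build_mixing(cfg.forward)
    windows = analysis_windows(cfg.timing)
    results, behavior_tables = [], []

    @_stage("simulate")
    def _simulate(s):
        return simulate_subject(
            cfg.design, cfg.effects, cfg.forward, cfg.timing, subject=s,
            seed=cfg.stage_seed("simulate", s),
            n_trials_train=cfg.trials_per_phase,
            n_trials_test=cfg.trials_per_phase, mixing=mixing)

    @_stage("preprocess")
    def _preprocess(epochs, s):
        epochs, _report = detect_muscle_artifacts(epochs)
        keep, _ = reject_eye(epochs)
        return epochs.select_trials(keep)

    @_stage("encode")
    def _encode(trials, ep_train, ep_test, s):
        model = SpatialEncodingModel.from_epochs(
            trials, ep_train, ep_test, band=cfg.band, order=cfg.filter_order,
            mode=cfg.mode, kind=cfg.power_kind, hpl_bin=cfg.design.hpl_bin,
            smooth_window=cfg.smooth_window, n_components=cfg.n_components)
        return model.fit(n_iter=cfg.n_iterations,
                         seed=cfg.stage_seed("encode", s))

    for s in range(cfg.n_subjects):
        trials, ep_train, ep_test = _simulate(s)
        if preprocess:
            ep_train = _preprocess(ep_train, s)
            ep_test = _preprocess(ep_test, s)
        results.append(_encode(trials, ep_train, ep_test, s))
        behavior_tables.append(trials)

    group = GroupResults(results)
    neural = {}
    for name, win in windows.items():
        res = group.cluster_test(win, n_perm=cfg.n_permutations,
                                 alpha=cfg.alpha,
                                 seed=cfg.stage_seed("cluster", 0))
        sl = group._window_slice(win)
        neural[name] = {
            "window_s": list(win),
            "mean_slope": float(group.slopes("grand")[:, sl].mean()),
            "cluster_pvals": res.pvals,
            "n_significant_clusters": len(res.significant_clusters),
        }
    gradient = None
    if "ping" in windows:
        gres = group.gradient_test(windows["ping"], n_perm=cfg.n_permutations,
                                   alpha=cfg.alpha,
                                   seed=cfg.stage_seed("gradient", 0))
        gradient = {
            "window_s": list(windows["ping"]),
            "mean_coef": float(gres.coefs.mean()),
            "cluster_pvals": gres.cluster.pvals,
            "n_significant_clusters": len(gres.cluster.significant_clusters),
            "significant_masses": [float(m) for m, p in
                                   zip(gres.cluster.masses, gres.cluster.pvals)
                                   if p <= cfg.alpha],
        }

    @_stage("behavior")
    def _behavior():
        trials_all = pd.concat(behavior_tables, ignore_index=True)
        summary = stats_tests(condition_summary(trials_all, cfg.design.hpl_bin))
        return trials_all, summary

    trials_all, behav = _behavior()

    import scipy
    cfg_yaml = json.dumps(_jsonable(asdict(cfg)), sort_keys=True)
    report = {
        "provenance": {
            "package": f"pingmap {__version__}",
            "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "master_seed": cfg.seed,
            "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                         "pandas": pd.__version__},
        },
        "config": json.loads(cfg_yaml),
        "neural": {"slopes": neural, "gradient": gradient,
                   "kind": cfg.power_kind, "mode": cfg.mode},
        "behavior": {
            "mean_rt_ms": behav.rt.mean().to_dict(),
            "mean_accuracy_pct": behav.accuracy.mean().to_dict(),
            "tests": behav.tests,
        },
    }
    report = _jsonable(report)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        write_trials(trials_all, out_dir / "trials.csv")
    return report
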