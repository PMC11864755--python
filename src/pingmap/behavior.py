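"""Behavioral analysis of the embedded additional-singleton search task.

RTs are trimmed (incorrect responses out, RT < 200 ms out, then a
per-subject +/-2.5 SD cut on the condition-collapsed distribution), trials
are categorized by distractor condition, target location, circular distance
of the distractor from the high-probability location (HPL), and distractor
repetition, and condition means are compared with paired t tests and a
repeated-measures ANOVA with Greenhouse-Geisser correction.

A trial counts as low-probability (LPL) only when neither the distractor
nor the target occupies the HPL; otherwise the known cost of a
target-at-HPL trial would contaminate the LPL baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import circular_distance_bins

__all__ = ["BehaviorSummary", "trim_rts", "condition_summary", "stats_tests"]


def _search_trials(trials: pd.DataFrame) -> pd.DataFrame:
    out = trials[(trials["phase"] == "test") & trials["rt"].notna()]
    return out


def trim_rts(trials: pd.DataFrame, min_rt: float = 200.0,
             sd_mult: float = 2.5) -> tuple[pd.DataFrame, dict]:
    """Exclude incorrect responses, anticipations, and per-subject outliers.

    Incorrect responses and RTs below ``min_rt`` ms are dropped first; the
    per-subject mean and SD are then computed on what remains (collapsed
    across conditions) and trials outside mean +/- ``sd_mult`` * SD are
    dropped.  Returns the trimmed search trials and a log of exclusion
    fractions.
    """
    search = _search_trials(trials)
    n0 = len(search)
    correct = search[search["correct"].eq(True)]
    fast = correct[correct["rt"] >= min_rt]
    kept = []
    for _, grp in fast.groupby("subject"):
        mu, sd = grp["rt"].mean(), grp["rt"].std(ddof=1)
        if not np.isfinite(sd):
            sd = 0.0
        lo, hi = mu - sd_mult * sd, mu + sd_mult * sd
        kept.append(grp[(grp["rt"] >= lo) & (grp["rt"] <= hi)])
    trimmed = pd.concat(kept) if kept else fast.iloc[:0]
    log = {
        "n_search": n0,
        "n_incorrect": n0 - len(correct),
        "n_fast": len(correct) - len(fast),
        "n_outlier": len(fast) - len(trimmed),
        "fraction_lost": 1.0 - len(trimmed) / n0 if n0 else 0.0,
    }
    return trimmed, log


def _categorize(search: pd.DataFrame, hpl_bin: int) -> pd.DataFrame:
    out = search.copy()
    dbin = out["distractor_bin"]
    tbin = out["target_bin"]
    present = dbin.notna()
    out["distractor_cond"] = "absent"
    out.loc[present & (dbin == hpl_bin), "distractor_cond"] = "hpl"
    lpl = present & (dbin != hpl_bin) & (tbin != hpl_bin)
    out.loc[lpl, "distractor_cond"] = "lpl"
    # distractor present, away from the HPL, but target at the HPL: excluded
    # from the HPL/LPL contrast by the footnote rule
    out.loc[present & (dbin != hpl_bin) & (tbin == hpl_bin),
            "distractor_cond"] = "excluded"
    out["target_cond"] = np.where(tbin == hpl_bin, "target_hpl", "target_lpl")
    out["distance"] = pd.array(
        np.where(present,
                 circular_distance_bins(dbin.fillna(0).to_numpy(dtype=int), hpl_bin),
                 -1), dtype="Int64")
    out.loc[~present, "distance"] = pd.NA
    # distance groups 1-4 inherit the footnote exclusion
    out["distance_group"] = out["distance"]
    out.loc[out["distractor_cond"] == "excluded", "distance_group"] = pd.NA

    # repetition: among consecutive distractor-present pairs within a subject
    prev_dbin = dbin.groupby(out["subject"]).shift(1)
    both = present & prev_dbin.notna()
    out["repetition"] = pd.NA
    out.loc[both & (dbin == prev_dbin), "repetition"] = "repeat"
    out.loc[both & (dbin != prev_dbin), "repetition"] = "nonrepeat"
    return out


@dataclass
class BehaviorSummary:
    """Per-subject condition means plus (after stats_tests) test statistics."""

    rt: pd.DataFrame                 # subjects x conditions, ms
    accuracy: pd.DataFrame           # subjects x conditions, percent
    counts: pd.DataFrame
    hpl_bin: int
    tests: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Behavioral summary (per-subject means averaged over "
                 f"{len(self.rt)} subjects; HPL bin {self.hpl_bin})"]
        lines.append("\nMean RT (ms):")
        lines.append(self.rt.mean().round(1).to_string())
        lines.append("\nMean accuracy (%):")
        lines.append(self.accuracy.mean().round(1).to_string())
        for name, res in self.tests.items():
            if "t" in res:
                lines.append(
                    f"\n{name}: t({res['df']}) = {res['t']:.2f}, "
                    f"p = {res['p']:.4g}, d = {res['d']:.2f}")
            elif "F" in res:
                lines.append(
                    f"\n{name}: F({res['df1']:.2f}, {res['df2']:.2f}) = "
                    f"{res['F']:.2f}, p-GG = {res['p_gg']:.4g}, "
                    f"eps = {res['eps']:.2f}, partial eta2 = {res['np2']:.2f}")
        return "\n".join(lines)


def condition_summary(trials: pd.DataFrame, hpl_bin: int) -> BehaviorSummary:
    """Per-subject mean RT and accuracy for every condition contrast.

    RT means use trimmed trials (see :func:`trim_rts`); accuracy uses all
    search trials.  Columns: distractor absent / hpl / lpl, target_hpl /
    target_lpl (collapsed over distractor presence), dist0..dist4, repeat /
    nonrepeat.
    """
    n_locations = 8
    if not 0 <= hpl_bin < n_locations:
        raise ValueError(f"unknown hpl_bin {hpl_bin}")
    search_all = _categorize(_search_trials(trials), hpl_bin)
    trimmed, trim_log = trim_rts(trials)
    trimmed = _categorize(trimmed, hpl_bin)

    def _means(df: pd.DataFrame, value: str, scale: float = 1.0) -> pd.DataFrame:
        cols = {}
        cols.update({c: df[df["distractor_cond"] == c].groupby("subject")[value].mean()
                     for c in ("absent", "hpl", "lpl")})
        cols.update({c: df[df["target_cond"] == c].groupby("subject")[value].mean()
                     for c in ("target_hpl", "target_lpl")})
        for d in range(5):
            cols[f"dist{d}"] = (df[df["distance_group"] == d]
                                .groupby("subject")[value].mean())
        cols.update({c: df[df["repetition"] == c].groupby("subject")[value].mean()
                     for c in ("repeat", "nonrepeat")})
        return pd.DataFrame(cols) * scale

    rt = _means(trimmed, "rt")
    acc = _means(search_all.assign(correct_num=search_all["correct"]
                                   .astype(float)), "correct_num", 100.0)
    counts = (search_all.groupby(["subject", "distractor_cond"])
              .size().unstack(fill_value=0))
    summary = BehaviorSummary(rt=rt, accuracy=acc, counts=counts,
                              hpl_bin=hpl_bin)
    summary.tests["trim_log"] = trim_log
    return summary


def _paired_t(a: np.ndarray, b: np.ndarray) -> dict:
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        t, p = 0.0, 1.0
        d = 0.0
    else:
        t, p = scipy.stats.ttest_rel(a, b)
        d = diff.mean() / sd
    return {"t": float(t), "p": float(p), "df": n - 1, "d": float(d),
            "mean_diff": float(diff.mean())}


def stats_tests(summary: BehaviorSummary, alpha: float = 0.05) -> BehaviorSummary:
    """Planned paired t tests and the distance repeated-measures ANOVA.

    Fills ``summary.tests`` with: HPL-vs-LPL distractor contrasts (RT and
    accuracy), target-at-HPL vs target-at-LPL, repetition contrast, the
    one-way repeated-measures ANOVA over distances 1-4 with
    Greenhouse-Geisser-corrected p and partial eta squared, and
    Holm-Bonferroni-corrected pairwise follow-ups among the distance
    levels.
    """
    if len(summary.rt) < 2:
        raise ValueError("need at least 2 subjects")
    rt, acc = summary.rt, summary.accuracy
    tests = summary.tests
    tests["rt_distractor_hpl_vs_lpl"] = _paired_t(rt["hpl"], rt["lpl"])
    tests["acc_distractor_hpl_vs_lpl"] = _paired_t(acc["hpl"], acc["lpl"])
    tests["rt_target_hpl_vs_lpl"] = _paired_t(rt["target_hpl"], rt["target_lpl"])
    tests["acc_target_hpl_vs_lpl"] = _paired_t(acc["target_hpl"], acc["target_lpl"])
    tests["rt_repeat_vs_nonrepeat"] = _paired_t(rt["repeat"], rt["nonrepeat"])

    for name, frame in (("rt", rt), ("acc", acc)):
        dist_cols = [f"dist{d}" for d in range(1, 5)]
        long = (frame[dist_cols].reset_index()
                .melt(id_vars="subject", var_name="distance", value_name="y"))
        aov = pg.rm_anova(data=long, dv="y", within="distance",
                          subject="subject", correction=True, detailed=True,
                          effsize="np2")
        row, err = aov.iloc[0], aov.iloc[1]
        eps = float(row["eps"]) if np.isfinite(row.get("eps", np.nan)) else 1.0
        p_gg = (float(row["p_GG_corr"])
                if np.isfinite(row.get("p_GG_corr", np.nan))
                else float(row["p_unc"]))
        tests[f"{name}_distance_anova"] = {
            "F": float(row["F"]), "df1": float(row["DF"]) * eps,
            "df2": float(err["DF"]) * eps, "p_gg": p_gg, "eps": eps,
            "np2": float(row["np2"]),
        }
        pairs, raw_p = [], []
        for i in range(1, 5):
            for j in range(i + 1, 5):
                res = _paired_t(frame[f"dist{i}"], frame[f"dist{j}"])
                pairs.append((f"dist{i}_vs_dist{j}", res))
                raw_p.append(res["p"])
        adj = multipletests(raw_p, alpha=alpha, method="holm")[1]
        tests[f"{name}_distance_pairwise"] = {
            label: {**res, "p_holm": float(p)}
            for (label, res), p in zip(pairs, adj)}
    return summary
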