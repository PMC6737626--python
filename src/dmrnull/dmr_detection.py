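"""Signed t-statistic tracks and DMR calling with per-scaffold cutoffs.

The t statistic at CpG *j* compares group-mean smoothed levels:

    t_j = (mean2_j - mean1_j) / (SD_j * sqrt(1/n1 + 1/n2))

where ``SD_j`` is the pooled within-group standard deviation of smoothed
levels ("same" variance in both groups), floored at the ``qSd`` quantile of
all per-CpG SDs on the scaffold and then smoothed by a running mean over
``k`` consecutive CpGs.  The corrected statistic subtracts a slowly varying
trend (a running median over a ``25*k``-CpG window) so regional drifts in
mean difference do not masquerade as signal.

Candidate DMRs are maximal runs of consecutive CpGs whose corrected t lies
strictly beyond the scaffold's empirical 0.025/0.975 quantile cutoffs, with
a run broken whenever the gap between adjacent CpGs exceeds ``maxGap`` bp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import Design

__all__ = [
    "DMR_COLUMNS",
    "compute_tstat",
    "find_dmrs",
    "quality_filter",
    "write_dmr_bed",
]

DMR_COLUMNS = [
    "scaffold", "start", "end", "n", "width", "invdensity", "areaStat",
    "maxStat", "group1.mean", "group2.mean", "meanDiff", "tstat.sd",
    "all.mean", "log2fc", "direction",
]


def _running_mean(values: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean over k points, truncated at the ends."""
    n = len(values)
    half = k // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def compute_tstat(profiles: pd.DataFrame, design: Design, qsd: float = 0.75,
                  k: int = 101, local_correct: bool = True) -> pd.DataFrame:
    """Per-CpG signed t-statistic track from smoothed profiles.

    Returns columns ``scaffold, pos, mean_g1, mean_g2, mean_all, sd, tstat,
    tstat_corrected`` (without local correction the last two are equal).
    """
    n1, n2 = len(design.group1), len(design.group2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 samples per group: SD undefined otherwise")
    missing = [s for s in design.samples if s not in profiles.columns]
    if missing:
        raise ValueError(f"profiles missing sample columns: {missing}")
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    frames = []
    for scaffold, grp in profiles.groupby("scaffold", sort=False):
        s1 = grp[list(design.group1)].to_numpy(dtype=float)
        s2 = grp[list(design.group2)].to_numpy(dtype=float)
        mean1 = s1.mean(axis=1)
        mean2 = s2.mean(axis=1)
        var1 = s1.var(axis=1, ddof=1)
        var2 = s2.var(axis=1, ddof=1)
        pooled = np.sqrt(((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2))
        floor = np.quantile(pooled, qsd)
        sd = np.maximum(pooled, floor)
        sd = _running_mean(sd, k)
        diff = mean2 - mean1
        t = np.zeros_like(diff)
        ok = sd > 0
        t[ok] = diff[ok] / (sd[ok] * scale)
        # degenerate zero-variance loci with a difference: unbounded evidence
        deg = ~ok & (diff != 0)
        t[deg] = np.sign(diff[deg]) * np.inf
        if local_correct:
            trend = _running_median(t, 25 * k)
            t_corr = t - trend
        else:
            t_corr = t.copy()
        frames.append(pd.DataFrame({
            "scaffold": scaffold,
            "pos": grp["pos"].to_numpy(),
            "mean_g1": mean1,
            "mean_g2": mean2,
            "mean_all": np.concatenate([s1, s2], axis=1).mean(axis=1),
            "sd": sd,
            "tstat": t,
            "tstat_corrected": t_corr,
        }))
    if not frames:
        raise ValueError("empty profile set")
    return pd.concat(frames, ignore_index=True)


def _runs(mask: np.ndarray, pos: np.ndarray, max_gap: int):
    """Maximal runs of True, broken at inter-CpG gaps > max_gap bp."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(pos[idx]) > max_gap)) + 1
    for chunk in np.split(idx, breaks):
        yield chunk


def _dmr_record(scaffold: str, run: np.ndarray, pos: np.ndarray,
                track: pd.DataFrame) -> dict:
    p_first, p_last = int(pos[run[0]]), int(pos[run[-1]])
    start, end = p_first - 1, p_last  # 0-based half-open span over the run
    t = track["tstat_corrected"].to_numpy()[run]
    g1 = float(track["mean_g1"].to_numpy()[run].mean())
    g2 = float(track["mean_g2"].to_numpy()[run].mean())
    n = len(run)
    width = end - start
    return {
        "scaffold": scaffold,
        "start": start,
        "end": end,
        "n": n,
        "width": width,
        "invdensity": width / n,
        "areaStat": float(t.sum()),
        "maxStat": float(t[np.argmax(np.abs(t))]),
        "group1.mean": g1,
        "group2.mean": g2,
        "meanDiff": g1 - g2,
        "tstat.sd": float(np.std(t, ddof=1)) if n > 1 else 0.0,
        "all.mean": float(track["mean_all"].to_numpy()[run].mean()),
        "log2fc": float(np.log2(g2 / g1)) if g1 > 0 and g2 > 0 else np.nan,
        "direction": "D-higher" if g2 > g1 else "ND-higher",
    }


def find_dmrs(tstat_track: pd.DataFrame, lower_q: float = 0.025,
              upper_q: float = 0.975, max_gap: int = 300,
              stat: str = "tstat_corrected") -> pd.DataFrame:
    """Call candidate DMRs from a t-statistic track.

    Cutoffs are the empirical ``lower_q``/``upper_q`` quantiles of the
    chosen statistic *on each scaffold*; a DMR is a maximal run of CpGs all
    strictly above the upper cutoff (or all strictly below the lower one).
    """
    if tstat_track.empty:
        raise ValueError("empty t-statistic track")
    records = []
    for scaffold, grp in tstat_track.groupby("scaffold", sort=False):
        grp = grp.reset_index(drop=True)
        t = grp[stat].to_numpy()
        pos = grp["pos"].to_numpy()
        cut_lo, cut_hi = np.quantile(t, [lower_q, upper_q])
        for run in _runs(t > cut_hi, pos, max_gap):
            records.append(_dmr_record(scaffold, run, pos, grp))
        for run in _runs(t < cut_lo, pos, max_gap):
            records.append(_dmr_record(scaffold, run, pos, grp))
    dmrs = pd.DataFrame(records, columns=DMR_COLUMNS)
    return (dmrs.sort_values(["scaffold", "start"], kind="mergesort")
                .reset_index(drop=True))


def quality_filter(dmrs: pd.DataFrame, min_n: int = 3,
                   min_abs_meandiff: float = 0.1) -> pd.DataFrame:
    """Remove DMRs with fewer than ``min_n`` measured CpGs or an absolute
    mean methylation difference below ``min_abs_meandiff``."""
    keep = ((dmrs["n"] >= min_n) &
            (dmrs["meanDiff"].abs() >= min_abs_meandiff))
    return dmrs.loc[keep].reset_index(drop=True)


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6 export; score = |areaStat| capped at 1000, strand '.'."""
    with open(path, "w") as fh:
        for i, row in dmrs.reset_index(drop=True).iterrows():
            score = int(min(abs(row["areaStat"]), 1000))
            fh.write(f"{row['scaffold']}\t{row['start']}\t{row['end']}\t"
                     f"dmr{i}\t{score}\t.\n")
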