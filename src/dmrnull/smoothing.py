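"""Local-likelihood smoothing of CpG methylation ratios, per scaffold.

Each sample's raw ratios (meth/total at every retained CpG) are replaced by
"methylation levels": fitted success probabilities from a weighted local
binomial regression.  At each CpG *j* the window is the smallest symmetric
neighbourhood containing at least ``ns`` CpGs and spanning at least ``h``
total bp (truncated at scaffold ends); within it a degree-2 polynomial in genomic
position is fitted to the binomial log-likelihood

    L(beta) = sum_i K_i * [ m_i * eta_i - t_i * log(1 + exp(eta_i)) ]

where ``K_i`` is a tricube kernel in distance scaled to the realized window
radius and ``eta = X beta`` on the logit scale.  The coverage weighting the
procedure requires is carried by the counts themselves: each locus
contributes in proportion to ``t_i``.  The fit is maximized by iteratively
reweighted least squares with step-halving (tolerance 1e-8, max 50
iterations); a degenerate window (zero genomic span) falls back to the
coverage-weighted window mean.

Scaffolds are smoothed independently; ``maxGap`` defaults to 1e8 bp so a
scaffold is never split internally, mirroring per-chromosome smoothing on
an assembly whose longest scaffold is a few Mb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .io_formats import Design, sample_ids

__all__ = [
    "SmoothingParams",
    "PARAMETER_GRID",
    "DEFAULT_PARAMS",
    "retain_loci",
    "retain_scaffolds",
    "smooth",
    "smooth_all_samples",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoothingParams:
    """Window controls: ns = minimum CpGs per window, h = minimum total
    width of the window in bp."""

    ns: int = 70
    h: int = 1000
    max_gap: int = 10 ** 8

    def __post_init__(self) -> None:
        if self.ns < 1 or self.h < 1 or self.max_gap < 1:
            raise ValueError("ns, h and max_gap must all be >= 1")

    @property
    def tag(self) -> str:
        return f"ns{self.ns}_h{self.h}"


#: The 3x3 grid used for the consensus filter; first cell is the default.
PARAMETER_GRID: tuple[SmoothingParams, ...] = tuple(
    SmoothingParams(ns=ns, h=h) for ns in (70, 50, 25) for h in (1000, 750, 500)
)
DEFAULT_PARAMS = PARAMETER_GRID[0]


def retain_loci(cpg_table: pd.DataFrame, min_depth: int = 4) -> pd.DataFrame:
    """Keep loci with total coverage >= min_depth in *every* sample.

    min_depth=4 is the methratio reporting threshold the study used; the
    comparison is inclusive (>=).
    """
    totals = cpg_table[[c for c in cpg_table.columns if c.startswith("total_")]]
    keep = (totals.to_numpy() >= min_depth).all(axis=1)
    return cpg_table.loc[keep].reset_index(drop=True)


def retain_scaffolds(cpg_table: pd.DataFrame, min_cpgs: int = 70) -> pd.DataFrame:
    """Drop scaffolds with fewer than ``min_cpgs`` retained loci.

    Scaffolds below the largest grid value of ``ns`` have undefined smoothed
    estimates in those runs, so they are excluded outright.
    """
    counts = cpg_table.groupby("scaffold", sort=False)["pos"].transform("size")
    return cpg_table.loc[counts.to_numpy() >= min_cpgs].reset_index(drop=True)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fit_window(x, m, t, k, eta_init):  # pragma: no cover - jitted
    """Maximize the tricube-weighted binomial log-likelihood of a quadratic
    logit model; return fitted probability at x = 0."""
    nw = x.shape[0]
    X = np.empty((nw, 3))
    for i in range(nw):
        X[i, 0] = 1.0
        X[i, 1] = x[i]
        X[i, 2] = x[i] * x[i]

    beta = np.zeros(3)
    beta[0] = eta_init

    def loglik(beta):
        ll = 0.0
        for i in range(nw):
            eta = beta[0] + beta[1] * x[i] + beta[2] * x[i] * x[i]
            if eta > 30.0:
                log1p = eta
            elif eta < -30.0:
                log1p = 0.0
            else:
                log1p = np.log(1.0 + np.exp(eta))
            ll += k[i] * (m[i] * eta - t[i] * log1p)
        return ll

    ll_old = loglik(beta)
    XtWX = np.empty((3, 3))
    XtWz = np.empty(3)
    for _ in range(50):
        for a in range(3):
            XtWz[a] = 0.0
            for b in range(3):
                XtWX[a, b] = 0.0
        for i in range(nw):
            eta = beta[0] + beta[1] * x[i] + beta[2] * x[i] * x[i]
            if eta > 30.0:
                p = 1.0 - 1e-13
            elif eta < -30.0:
                p = 1e-13
            else:
                p = 1.0 / (1.0 + np.exp(-eta))
            v = p * (1.0 - p)
            if v < 1e-12:
                v = 1e-12
            w = k[i] * t[i] * v
            z = eta + (m[i] - t[i] * p) / (t[i] * v)
            for a in range(3):
                xa = X[i, a]
                XtWz[a] += w * xa * z
                for b in range(3):
                    XtWX[a, b] += w * xa * X[i, b]
        # mild ridge keeps near-collinear designs solvable
        ridge = 1e-9 * (XtWX[0, 0] + XtWX[1, 1] + XtWX[2, 2]) + 1e-300
        for a in range(3):
            XtWX[a, a] += ridge
        beta_new = np.linalg.solve(XtWX, XtWz)
        # step-halving safeguard: never accept a likelihood decrease
        step = 1.0
        accepted = False
        for _half in range(30):
            trial = beta + step * (beta_new - beta)
            ll_new = loglik(trial)
            if ll_new >= ll_old - 1e-12:
                beta = trial
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        delta = abs(ll_new - ll_old)
        ll_old = ll_new
        if delta < 1e-10 * (abs(ll_old) + 1.0):
            break

    eta0 = beta[0]
    if eta0 > 30.0:
        return 1.0
    if eta0 < -30.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-eta0))


@njit(cache=True)
def _smooth_scaffold(pos, meth, total, ns, h):  # pragma: no cover - jitted
    n = pos.shape[0]
    out = np.empty(n)
    span_min = float(h)  # h = minimum *total* bases in the window
    half = 0.5 * h
    for j in range(n):
        lo = j
        hi = j
        while (hi - lo + 1 < ns) or (pos[hi] - pos[lo] < span_min):
            grew = False
            if lo > 0:
                lo -= 1
                grew = True
            if hi < n - 1:
                hi += 1
                grew = True
            if not grew:
                break
        nw = hi - lo + 1
        # realized radius for kernel scaling (>= h/2 by construction)
        r = max(pos[j] - pos[lo], pos[hi] - pos[j], half) * (1.0 + 1e-9)
        x = np.empty(nw)
        m = np.empty(nw)
        t = np.empty(nw)
        k = np.empty(nw)
        all0 = True
        all1 = True
        tot_w = 0.0
        wsum = 0.0
        for i in range(nw):
            d = abs(pos[lo + i] - pos[j]) / r
            u = 1.0 - d * d * d
            k[i] = u * u * u if u > 0.0 else 0.0
            x[i] = (pos[lo + i] - pos[j]) / r
            m[i] = meth[lo + i]
            t[i] = total[lo + i]
            if k[i] > 0.0:
                if m[i] > 0.0:
                    all0 = False
                if m[i] < t[i]:
                    all1 = False
            tot_w += k[i] * t[i]
            wsum += k[i] * m[i]
        if all0:
            out[j] = 0.0
            continue
        if all1:
            out[j] = 1.0
            continue
        if pos[hi] - pos[lo] <= 0.0 or tot_w <= 0.0:
            # degenerate window: coverage-weighted mean of raw ratios
            out[j] = wsum / tot_w if tot_w > 0.0 else 0.5
            continue
        pbar = wsum / tot_w
        if pbar <= 0.0:
            pbar = 1e-6
        elif pbar >= 1.0:
            pbar = 1.0 - 1e-6
        eta0 = np.log(pbar / (1.0 - pbar))
        p = _fit_window(x, m, t, k, eta0)
        if p < 0.0:
            p = 0.0
        elif p > 1.0:
            p = 1.0
        out[j] = p
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def smooth(cpg_table: pd.DataFrame, params: SmoothingParams,
           sample_id: str) -> pd.DataFrame:
    """Smooth one sample over every scaffold of a retained CpG table.

    Returns a frame with columns ``scaffold``, ``pos`` and the sample id
    holding smoothed levels in [0, 1].  Scaffolds with fewer than
    ``params.ns`` loci are skipped with a log entry.
    """
    frames = []
    for scaffold, grp in cpg_table.groupby("scaffold", sort=False):
        if len(grp) < params.ns:
            logger.info("scaffold %s skipped: %d < ns=%d loci",
                        scaffold, len(grp), params.ns)
            continue
        pos = grp["pos"].to_numpy(dtype=np.float64)
        meth = grp[f"meth_{sample_id}"].to_numpy(dtype=np.float64)
        total = grp[f"total_{sample_id}"].to_numpy(dtype=np.float64)
        levels = _smooth_scaffold(pos, meth, total, params.ns, params.h)
        frames.append(pd.DataFrame({"scaffold": scaffold,
                                    "pos": grp["pos"].to_numpy(),
                                    sample_id: levels}))
    if not frames:
        return pd.DataFrame(columns=["scaffold", "pos", sample_id])
    return pd.concat(frames, ignore_index=True)


def smooth_all_samples(cpg_table: pd.DataFrame, params: SmoothingParams,
                       samples: Sequence[str] | None = None,
                       design: Design | None = None) -> pd.DataFrame:
    """Smoothed profile frame: scaffold, pos, one level column per sample."""
    if samples is None:
        samples = design.samples if design is not None else sample_ids(cpg_table)
    out: pd.DataFrame | None = None
    for s in samples:
        col = smooth(cpg_table, params, s)
        if out is None:
            out = col
        else:
            out = out.merge(col, on=["scaffold", "pos"], how="inner")
    if out is None:
        raise ValueError("no samples to smooth")
    return out
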