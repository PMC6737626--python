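"""Specificity filters for candidate DMRs.

Two bespoke filters guard against artifacts of the smoothing parameters and
against single-sample outliers:

* **Consensus**: DMRs are called under all nine (ns, h) smoothing-parameter
  combinations; a default-cell DMR survives only if every other cell calls
  a matching DMR (identical coordinates, or >= 100 bp shared span with the
  same direction of difference).
* **Label shuffle**: the whole grid is re-run under every balanced
  non-identity permutation of the group labels (two for a 2v2 design) and
  *every* quality-filtered DMR from every cell is pooled; a consensus DMR
  covered by any single shuffled DMR over at least half of its own width is
  discarded as likely driven by one extreme sample rather than the group
  contrast.

Hand curation is not automated; :func:`export_for_review` writes per-DMR
raw/smoothed tables so a human can do the final pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dmr_detection import compute_tstat, find_dmrs, quality_filter
from .io_formats import Design
from .smoothing import DEFAULT_PARAMS, PARAMETER_GRID, SmoothingParams, smooth_all_samples

__all__ = [
    "RunGrid",
    "run_grid",
    "consensus",
    "balanced_permutations",
    "shuffled_dmrs",
    "shuffle_filter",
    "export_for_review",
]


@dataclass
class RunGrid:
    """DMR calls for every cell of the smoothing-parameter grid."""

    cells: dict[SmoothingParams, pd.DataFrame]
    default: SmoothingParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        if len(self.cells) != 9:
            raise ValueError(f"expected 9 grid cells, got {len(self.cells)}")
        if self.default not in self.cells:
            raise ValueError("default cell missing from grid")


def _cell_dmrs(profiles: pd.DataFrame, design: Design, qsd: float, k: int,
               max_gap: int, min_n: int, min_abs_meandiff: float) -> pd.DataFrame:
    track = compute_tstat(profiles, design, qsd=qsd, k=k)
    return quality_filter(find_dmrs(track, max_gap=max_gap),
                          min_n=min_n, min_abs_meandiff=min_abs_meandiff)


def run_grid(cpg_table: pd.DataFrame, design: Design,
             grid: Sequence[SmoothingParams] = PARAMETER_GRID,
             profiles_by_cell: Mapping[SmoothingParams, pd.DataFrame] | None = None,
             qsd: float = 0.75, k: int = 101, max_gap: int = 300,
             min_n: int = 3, min_abs_meandiff: float = 0.1) -> RunGrid:
    """Call quality-filtered DMRs in every grid cell for one design.

    Smoothing is design-independent, so precomputed per-cell profiles may be
    supplied and reused across label permutations.
    """
    cells = {}
    for params in grid:
        if profiles_by_cell is not None and params in profiles_by_cell:
            profiles = profiles_by_cell[params]
        else:
            profiles = smooth_all_samples(cpg_table, params, design.samples)
        cells[params] = _cell_dmrs(profiles, design, qsd, k, max_gap,
                                   min_n, min_abs_meandiff)
    return RunGrid(cells=cells, default=grid[0])


def _overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def consensus(grid: RunGrid, min_overlap_bp: int = 100) -> pd.DataFrame:
    """DMRs supported in all nine grid cells, coordinates from the default.

    A match in another cell is either coordinate-identical or shares at
    least ``min_overlap_bp`` of span with the same direction.  The returned
    frame carries the default cell's statistics plus ``match_type`` (exact
    only when all eight supporting matches are exact).
    """
    default = grid.cells[grid.default]
    others = [grid.cells[p] for p in grid.cells if p != grid.default]
    keep_rows = []
    for _, d in default.iterrows():
        all_exact = True
        supported = True
        for cell in others:
            cand = cell[cell["scaffold"] == d["scaffold"]]
            exact = cand[(cand["start"] == d["start"]) & (cand["end"] == d["end"]) &
                         (cand["direction"] == d["direction"])]
            if len(exact):
                continue
            ov = cand.apply(
                lambda r: _overlap_bp(d["start"], d["end"], r["start"], r["end"]),
                axis=1) if len(cand) else pd.Series(dtype=float)
            hit = cand[(ov >= min_overlap_bp) &
                       (cand["direction"] == d["direction"])] if len(cand) else cand
            if len(hit) == 0:
                supported = False
                break
            all_exact = False
        if supported:
            row = d.copy()
            row["match_type"] = "exact" if all_exact else "overlap"
            keep_rows.append(row)
    if not keep_rows:
        return default.iloc[0:0].assign(match_type=pd.Series(dtype=str))
    return pd.DataFrame(keep_rows).reset_index(drop=True)


def balanced_permutations(design: Design) -> list[Design]:
    """All non-identity balanced relabelings, deduplicated up to group swap.

    For a 2v2 design this yields exactly the two shuffles of the study:
    {A1,B1} vs {A2,B2} and {A1,B2} vs {A2,B1}.
    """
    if len(design.group1) != len(design.group2):
        raise ValueError("shuffle filter requires a balanced design")
    samples = design.samples
    n1 = len(design.group1)
    identity = frozenset([frozenset(design.group1), frozenset(design.group2)])
    seen = {identity}
    out = []
    for combo in itertools.combinations(samples, n1):
        g1 = frozenset(combo)
        g2 = frozenset(s for s in samples if s not in g1)
        key = frozenset([g1, g2])
        if key in seen:
            continue
        seen.add(key)
        out.append(Design(sorted(g1), sorted(g2),
                          labels=("perm1", "perm2")))
    return out


def shuffled_dmrs(cpg_table: pd.DataFrame, design: Design,
                  grid: Sequence[SmoothingParams] = PARAMETER_GRID,
                  profiles_by_cell: Mapping[SmoothingParams, pd.DataFrame] | None = None,
                  **call_kwargs) -> pd.DataFrame:
    """Pool every quality-filtered DMR from every grid cell under every
    balanced label permutation ("shuffled" DMRs)."""
    pooled = []
    for perm in balanced_permutations(design):
        g = run_grid(cpg_table, perm, grid=grid,
                     profiles_by_cell=profiles_by_cell, **call_kwargs)
        for params, dmrs in g.cells.items():
            if len(dmrs):
                pooled.append(dmrs.assign(cell=params.tag))
    if not pooled:
        return pd.DataFrame(columns=["scaffold", "start", "end"])
    return pd.concat(pooled, ignore_index=True)


def _max_covered_fraction(dmr, shuffled: pd.DataFrame) -> float:
    cand = shuffled[shuffled["scaffold"] == dmr["scaffold"]]
    if not len(cand):
        return 0.0
    ov = np.minimum(cand["end"].to_numpy(), dmr["end"]) - \
        np.maximum(cand["start"].to_numpy(), dmr["start"])
    return float(np.max(ov.clip(min=0))) / (dmr["end"] - dmr["start"])


def shuffle_filter(consensus_dmrs: pd.DataFrame, cpg_table: pd.DataFrame,
                   design: Design, min_frac: float = 0.5,
                   grid: Sequence[SmoothingParams] = PARAMETER_GRID,
                   profiles_by_cell: Mapping[SmoothingParams, pd.DataFrame] | None = None,
                   shuffled: pd.DataFrame | None = None,
                   **call_kwargs) -> pd.DataFrame:
    """Remove consensus DMRs reproduced under shuffled group labels.

    A consensus DMR is removed when any single shuffled DMR covers at least
    ``min_frac`` of the consensus DMR's own width.  ``shuffled`` may be
    supplied directly; otherwise the permuted grids are computed here.
    """
    if shuffled is None:
        shuffled = shuffled_dmrs(cpg_table, design, grid=grid,
                                 profiles_by_cell=profiles_by_cell, **call_kwargs)
    if not len(consensus_dmrs) or not len(shuffled):
        return consensus_dmrs.reset_index(drop=True)
    frac = consensus_dmrs.apply(_max_covered_fraction, axis=1, shuffled=shuffled)
    return consensus_dmrs.loc[frac < min_frac].reset_index(drop=True)


def export_for_review(dmrs: pd.DataFrame, profiles: pd.DataFrame,
                      out_dir: str | Path, cpg_table: pd.DataFrame | None = None,
                      window_bp: int = 2000) -> pd.DataFrame:
    """Write one raw+smoothed table per DMR (± window) plus an index file.

    Replaces by-eye curation of each candidate with a reviewable bundle;
    window bounds are clamped at the available loci of the scaffold.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for i, d in dmrs.reset_index(drop=True).iterrows():
        lo, hi = max(d["start"] - window_bp, 0), d["end"] + window_bp
        scaf_prof = profiles[(profiles["scaffold"] == d["scaffold"]) &
                             (profiles["pos"] > lo) & (profiles["pos"] <= hi)]
        table = scaf_prof.copy()
        if cpg_table is not None:
            raw = cpg_table[(cpg_table["scaffold"] == d["scaffold"]) &
                            (cpg_table["pos"] > lo) & (cpg_table["pos"] <= hi)]
            table = table.merge(raw, on=["scaffold", "pos"], how="left")
        name = f"dmr{i}_{d['scaffold']}_{d['start']}_{d['end']}.tsv"
        table.to_csv(out_dir / name, sep="\t", index=False)
        index_rows.append({"dmr_id": f"dmr{i}", "scaffold": d["scaffold"],
                           "start": d["start"], "end": d["end"], "file": name})
    index = pd.DataFrame(index_rows,
                         columns=["dmr_id", "scaffold", "start", "end", "file"])
    index.to_csv(out_dir / "index.tsv", sep="\t", index=False)
    return index
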