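"""End-to-end DMR pipeline: filter -> smooth grid -> call -> consensus ->
label-shuffle filter."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import Design
from .robustness import RunGrid, consensus, run_grid, shuffle_filter, shuffled_dmrs
from .smoothing import PARAMETER_GRID, SmoothingParams, retain_loci, retain_scaffolds, smooth_all_samples

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    retained: pd.DataFrame           # coverage/scaffold-filtered CpG table
    profiles: dict                   # SmoothingParams -> smoothed profile frame
    grid: RunGrid                    # per-cell quality-filtered DMRs (true labels)
    consensus_dmrs: pd.DataFrame     # supported in all nine cells
    shuffled: pd.DataFrame           # pooled DMRs from label permutations
    dmrs: pd.DataFrame               # final: consensus minus shuffle hits

    @property
    def default_profiles(self) -> pd.DataFrame:
        return self.profiles[list(self.profiles)[0]]


def run_pipeline(cpg_table: pd.DataFrame, design: Design,
                 grid: Sequence[SmoothingParams] = PARAMETER_GRID,
                 min_depth: int = 4, min_cpgs: int = 70,
                 min_overlap_bp: int = 100, min_frac: float = 0.5,
                 qsd: float = 0.75, k: int = 101, max_gap: int = 300,
                 min_n: int = 3, min_abs_meandiff: float = 0.1) -> PipelineResult:
    """Run the full DMR analysis on a merged multi-sample CpG table.

    Per-sample smoothing is computed once per grid cell and shared between
    the true-label calls and the label permutations (smoothing does not see
    the design).
    """
    retained = retain_scaffolds(retain_loci(cpg_table, min_depth=min_depth),
                                min_cpgs=min_cpgs)
    profiles = {params: smooth_all_samples(retained, params, design.samples)
                for params in grid}
    call_kwargs = dict(qsd=qsd, k=k, max_gap=max_gap, min_n=min_n,
                       min_abs_meandiff=min_abs_meandiff)
    true_grid = run_grid(retained, design, grid=grid,
                         profiles_by_cell=profiles, **call_kwargs)
    cons = consensus(true_grid, min_overlap_bp=min_overlap_bp)
    shuf = shuffled_dmrs(retained, design, grid=grid,
                         profiles_by_cell=profiles, **call_kwargs)
    final = shuffle_filter(cons, retained, design, min_frac=min_frac,
                           shuffled=shuf)
    return PipelineResult(retained=retained, profiles=profiles, grid=true_grid,
                          consensus_dmrs=cons, shuffled=shuf, dmrs=final)
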