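"""Bootstrap null intervals ("nullDMRs") and empirical p-values.

A null replicate redistributes the real DMRs across the genome while
preserving two things: the per-scaffold density (scaffold names are drawn
with replacement with probability proportional to each scaffold's real DMR
count) and the width distribution (the real width multiset is randomly
permuted onto the drawn scaffolds, each width then placed uniformly within
its scaffold).  Repeating this (10,000 sets in the study) gives an
empirical null for any scalar statistic of an interval set; the p-value is
the fraction of null sets that met or exceeded the observed value, reported
as ``< 1/n_sets`` when none did.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeIndex

__all__ = [
    "NullDMRSet",
    "EmpiricalP",
    "sample_null_set",
    "sample_null_sets",
    "empirical_pvalue",
    "null_statistic_battery",
]


@dataclass
class NullDMRSet:
    replicate_id: int
    intervals: pd.DataFrame  # scaffold, start, end


@dataclass(frozen=True)
class EmpiricalP:
    """Bootstrap p-value: exceedance fraction with a zero-count sentinel."""

    observed: float
    direction: str           # "ge" (enrichment) or "le" (depletion)
    exceedances: int
    n_sets: int

    @property
    def p(self) -> float:
        return self.exceedances / self.n_sets

    @property
    def is_floor(self) -> bool:
        return self.exceedances == 0

    def __str__(self) -> str:
        if self.is_floor:
            return f"p < {1.0 / self.n_sets:g}"
        return f"p = {self.p:g}"


def _replicate_rng(seed: int, replicate_id: int) -> np.random.Generator:
    """Independent, reproducible substream per replicate (Philox keyed on
    (seed, replicate))."""
    return np.random.Generator(np.random.Philox(key=[seed, replicate_id]))


def sample_null_set(dmrs: pd.DataFrame, genome_index: GenomeIndex,
                    rng_seed: int, replicate_id: int = 0,
                    max_retries: int = 1000) -> NullDMRSet:
    """One density-weighted, width-preserving random interval set.

    Scaffolds with zero real DMRs get zero weight.  If a drawn scaffold is
    shorter than the width assigned to it, the scaffold is redrawn for that
    width (bounded retries), a necessary edge rule on fragmented assemblies.
    """
    if not len(dmrs):
        raise ValueError("no real DMRs to match")
    counts = dmrs["scaffold"].value_counts()
    scaffolds = counts.index.to_numpy()
    for s in scaffolds:
        if s not in genome_index:
            raise ValueError(f"scaffold {s!r} missing from genome index")
    weights = counts.to_numpy(dtype=float)
    weights /= weights.sum()
    lengths = np.array([genome_index.lengths[s] for s in scaffolds])
    widths = (dmrs["end"] - dmrs["start"]).to_numpy()
    if widths.max() > lengths.max():
        raise ValueError("a DMR width exceeds every weighted scaffold")

    rng = _replicate_rng(rng_seed, replicate_id)
    draw = rng.choice(len(scaffolds), size=len(widths), p=weights)
    shuffled_widths = rng.permutation(widths)
    rows = []
    for idx, width in zip(draw, shuffled_widths):
        tries = 0
        while lengths[idx] < width:
            tries += 1
            if tries > max_retries:
                raise RuntimeError(
                    f"could not place width {width} after {max_retries} redraws")
            idx = rng.choice(len(scaffolds), p=weights)
        start = int(rng.integers(0, lengths[idx] - width + 1))
        rows.append((scaffolds[idx], start, start + int(width)))
    intervals = pd.DataFrame(rows, columns=["scaffold", "start", "end"])
    return NullDMRSet(replicate_id=replicate_id, intervals=intervals)


def sample_null_sets(dmrs: pd.DataFrame, genome_index: GenomeIndex,
                     n_sets: int, rng_seed: int) -> Iterable[NullDMRSet]:
    """Generate ``n_sets`` independent null replicates (lazily)."""
    for rep in range(n_sets):
        yield sample_null_set(dmrs, genome_index, rng_seed, replicate_id=rep)


def empirical_pvalue(observed: float, null_values: Sequence[float],
                     direction: str = "ge") -> EmpiricalP:
    """Fraction of null sets meeting/exceeding the observed value.

    Ties count against significance (the comparison is inclusive); zero
    exceedances are reported as the ``< 1/n`` floor, never as p = 0.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("null_values must be nonempty")
    if direction == "ge":
        exceed = int(np.sum(null_values >= observed))
    elif direction == "le":
        exceed = int(np.sum(null_values <= observed))
    else:
        raise ValueError(f"direction must be 'ge' or 'le', got {direction!r}")
    return EmpiricalP(observed=float(observed), direction=direction,
                      exceedances=exceed, n_sets=int(null_values.size))


def null_statistic_battery(
    dmrs: pd.DataFrame,
    null_sets: Iterable[NullDMRSet | pd.DataFrame],
    statistics: Mapping[str, Callable[[pd.DataFrame], float]],
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Empirical p for each pluggable interval-set statistic.

    ``statistics`` maps a name to a function taking an interval frame
    (scaffold/start/end) and returning a scalar, e.g. the number of
    intervals overlapping a gene.  ``directions`` selects 'ge' (enrichment,
    default) or 'le' (depletion; the convention used for TE overlaps, where
    the question is whether null sets show *fewer* hits).
    """
    directions = dict(directions or {})
    observed = {}
    for name, fn in statistics.items():
        try:
            observed[name] = float(fn(dmrs))
        except Exception as exc:
            raise RuntimeError(f"statistic {name!r} failed on real DMRs: {exc}") from exc
    null_values: dict[str, list[float]] = {name: [] for name in statistics}
    for rep_i, ns in enumerate(null_sets):
        intervals = ns.intervals if isinstance(ns, NullDMRSet) else ns
        for name, fn in statistics.items():
            try:
                null_values[name].append(float(fn(intervals)))
            except Exception as exc:
                raise RuntimeError(
                    f"statistic {name!r} failed on null replicate {rep_i}: {exc}"
                ) from exc
    rows = []
    for name in statistics:
        ep = empirical_pvalue(observed[name], null_values[name],
                              direction=directions.get(name, "ge"))
        rows.append({"statistic": name, "observed": ep.observed,
                     "direction": ep.direction, "exceedances": ep.exceedances,
                     "n_sets": ep.n_sets, "p": ep.p, "is_floor": ep.is_floor,
                     "p_report": str(ep)})
    return pd.DataFrame(rows)
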