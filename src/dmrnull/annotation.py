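"""Feature geometry around DMRs.

Covers the annotation layer: basal regulatory regions (5 kb up- to 1 kb
downstream of the TSS, and 1 kb up- to 5 kb downstream of the 3' end,
strand-aware), the three regulatory-hit types

* type-1 — within 5 kb of a gene (in a regulatory region) but outside the
  body entirely,
* type-2 — overlapping the first or last 1 kb of a gene body,
* type-3 — a type-1/2 hit for one gene that also lies within the body of a
  different gene on the opposite strand,

plus overlap and distance tables against gene bodies, exons (coding vs
non-coding), introns, TEs, CNEs and lncRNAs, GC content, and PWM scanning
with the relative-score > 90% rule.  All intervals are 0-based half-open;
overlap means at least one shared bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomeIndex

__all__ = [
    "FeatureSet",
    "derive_regulatory_regions",
    "classify_regulatory_hits",
    "overlap_table",
    "OVERLAP_CLASSES",
    "distance_table",
    "gc_content",
    "PWM",
    "read_jaspar",
    "pwm_scan",
]

FLANK_BP = 5000
INTO_BODY_BP = 1000
EDGE_BP = 1000


# ---------------------------------------------------------------------------
# feature container
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Strand-aware gene/exon/intron/TE/CNE/lncRNA intervals on scaffolds.

    ``genes`` columns: gene_id, scaffold, start, end, strand, coding,
    lncrna, n_isoforms.  ``exons`` add transcript_id and a coding flag;
    ``tes``/``cnes`` are plain interval frames (may be None).
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    introns: pd.DataFrame
    tes: pd.DataFrame | None = None
    cnes: pd.DataFrame | None = None
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        bad = self.genes[~self.genes["strand"].isin(["+", "-"])]
        if len(bad):
            raise ValueError(f"genes with unknown strand: {list(bad.gene_id)}")

    @property
    def regulatory_regions(self) -> pd.DataFrame:
        """Per-gene 5'/3' basal regulatory regions (clamped at 0)."""
        rows = []
        for _, g in self.genes.iterrows():
            five, three = derive_regulatory_regions(g.start, g.end, g.strand)
            rows.append((g.gene_id, g.scaffold, "5p", *five))
            rows.append((g.gene_id, g.scaffold, "3p", *three))
        return pd.DataFrame(rows, columns=["gene_id", "scaffold", "side",
                                           "start", "end"])

    def tree(self, kind: str) -> Mapping[str, IntervalTree]:
        """Per-scaffold interval trees for a feature class (cached)."""
        if kind in self._trees:
            return self._trees[kind]
        if kind == "gene_body":
            df = self.genes.rename(columns={"gene_id": "name"})
        elif kind == "lncrna":
            df = self.genes[self.genes["lncrna"]].rename(columns={"gene_id": "name"})
        elif kind == "exon_coding":
            df = self.exons[self.exons["coding"]]
        elif kind == "exon_noncoding":
            df = self.exons[~self.exons["coding"]]
        elif kind == "intron":
            df = self.introns
        elif kind in ("reg_5prime", "reg_3prime"):
            rr = self.regulatory_regions
            df = rr[rr["side"] == ("5p" if kind == "reg_5prime" else "3p")]
            df = df.rename(columns={"gene_id": "name"})
        elif kind in ("upstream", "downstream"):
            rows = []
            for _, g in self.genes.iterrows():
                up = kind == "upstream"
                left = (g.strand == "+") == up
                if left:
                    iv = (max(g.start - FLANK_BP, 0), g.start)
                else:
                    iv = (g.end, g.end + FLANK_BP)
                if iv[1] > iv[0]:
                    rows.append((g.gene_id, g.scaffold, iv[0], iv[1]))
            df = pd.DataFrame(rows, columns=["name", "scaffold", "start", "end"])
        elif kind == "te":
            df = self.tes if self.tes is not None else pd.DataFrame(
                columns=["scaffold", "start", "end"])
        elif kind == "cne":
            df = self.cnes if self.cnes is not None else pd.DataFrame(
                columns=["scaffold", "start", "end"])
        else:
            raise KeyError(kind)
        trees: dict[str, IntervalTree] = {}
        for _, row in df.iterrows():
            if row["end"] <= row["start"]:
                continue
            name = row["name"] if "name" in df.columns else None
            trees.setdefault(row["scaffold"], IntervalTree()).addi(
                row["start"], row["end"], name)
        self._trees[kind] = trees
        return trees


# ---------------------------------------------------------------------------
# regulatory regions and hit classification
# ---------------------------------------------------------------------------

def derive_regulatory_regions(start: int, end: int, strand: str,
                              scaffold_length: int | None = None
                              ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Basal regulatory regions for a gene span [start, end) on a strand.

    Plus strand: 5' = [TSS-5000, TSS+1000), 3' = [TES-1000, TES+5000);
    minus strand mirrored about its own TSS (= end) and TES (= start).
    Bounds are clamped to [0, scaffold_length).
    """
    if strand == "+":
        five = (start - FLANK_BP, start + INTO_BODY_BP)
        three = (end - INTO_BODY_BP, end + FLANK_BP)
    elif strand == "-":
        five = (end - INTO_BODY_BP, end + FLANK_BP)
        three = (start - FLANK_BP, start + INTO_BODY_BP)
    else:
        raise ValueError(f"unknown strand {strand!r}")

    def clamp(iv):
        lo, hi = max(iv[0], 0), iv[1]
        if scaffold_length is not None:
            hi = min(hi, scaffold_length)
        return (lo, hi)

    return clamp(five), clamp(three)


def _gene_edges(start: int, end: int, strand: str):
    """First (TSS-side) and last 1 kb of the gene body, along the genome."""
    left = (start, min(start + EDGE_BP, end))
    right = (max(end - EDGE_BP, start), end)
    return (left, right) if strand == "+" else (right, left)


def _ov(a0, a1, b0, b1) -> bool:
    return max(a0, b0) < min(a1, b1)


def classify_regulatory_hits(dmrs: pd.DataFrame,
                             features: FeatureSet) -> pd.DataFrame:
    """Type-1/2/3 regulatory hits for every (DMR, gene) pair.

    Returns columns ``dmr_index, gene_id, hit_type, side,
    antisense_body_gene_id`` where ``dmr_index`` is the positional index
    into ``dmrs``.  Type-3 rows are emitted in addition to their underlying
    type-1/2 row.
    """
    genes = features.genes
    rows = []
    for i, d in dmrs.reset_index(drop=True).iterrows():
        g_scaf = genes[genes["scaffold"] == d["scaffold"]]
        base_hits = []
        for _, g in g_scaf.iterrows():
            body = _ov(d["start"], d["end"], g.start, g.end)
            first, last = _gene_edges(g.start, g.end, g.strand)
            five, three = derive_regulatory_regions(g.start, g.end, g.strand)
            if body:
                if _ov(d["start"], d["end"], *first):
                    base_hits.append((g, 2, "5p"))
                if _ov(d["start"], d["end"], *last):
                    base_hits.append((g, 2, "3p"))
            else:
                if _ov(d["start"], d["end"], *five):
                    base_hits.append((g, 1, "5p"))
                if _ov(d["start"], d["end"], *three):
                    base_hits.append((g, 1, "3p"))
        for g, hit_type, side in base_hits:
            rows.append((i, g.gene_id, hit_type, side, None))
            for _, other in g_scaf.iterrows():
                if other.gene_id == g.gene_id or other.strand == g.strand:
                    continue
                if _ov(d["start"], d["end"], other.start, other.end):
                    rows.append((i, g.gene_id, 3, side, other.gene_id))
    return pd.DataFrame(rows, columns=["dmr_index", "gene_id", "hit_type",
                                       "side", "antisense_body_gene_id"])


# ---------------------------------------------------------------------------
# overlap / distance tables
# ---------------------------------------------------------------------------

OVERLAP_CLASSES = [
    "gene_body", "exon_coding", "exon_noncoding", "intron",
    "reg_5prime", "reg_3prime", "upstream", "downstream",
    "te", "cne", "lncrna",
]


def overlap_table(dmrs: pd.DataFrame, features: FeatureSet,
                  classes: Sequence[str] = OVERLAP_CLASSES) -> pd.DataFrame:
    """Per-DMR boolean overlap vector over feature classes, plus counts.

    Booleans use the >=1-shared-bp half-open rule; ``<class>_count``
    columns report how many distinct intervals of the class the DMR
    touches (e.g. the number of TEs inside a DMR).
    """
    out = {}
    for kind in classes:
        trees = features.tree(kind)
        flags, counts = [], []
        for _, d in dmrs.iterrows():
            tree = trees.get(d["scaffold"])
            n = len(tree.overlap(d["start"], d["end"])) if tree is not None else 0
            flags.append(n > 0)
            counts.append(n)
        out[kind] = flags
        out[f"{kind}_count"] = counts
    res = pd.DataFrame(out, index=dmrs.index)
    res.insert(0, "scaffold", dmrs["scaffold"].to_numpy())
    res.insert(1, "start", dmrs["start"].to_numpy())
    res.insert(2, "end", dmrs["end"].to_numpy())
    return res


def distance_table(dmrs: pd.DataFrame, genes: pd.DataFrame,
                   windows: Sequence[int] = (5000, 10000, 15000, 20000,
                                             25000, 30000)) -> pd.DataFrame:
    """Nearest-gene distance and per-window gene counts for each DMR.

    Distance is 0 on overlap, otherwise the gap in bp; NA when the DMR's
    scaffold carries no genes.  Window counts (genes within w bp) are
    non-decreasing in w by construction.
    """
    rows = []
    for _, d in dmrs.iterrows():
        g_scaf = genes[genes["scaffold"] == d["scaffold"]]
        rec = {"scaffold": d["scaffold"], "start": d["start"], "end": d["end"]}
        if not len(g_scaf):
            rec["nearest_gene"] = None
            rec["distance"] = np.nan
            for w in windows:
                rec[f"genes_within_{w}"] = 0
            rows.append(rec)
            continue
        gaps = np.maximum(
            np.maximum(g_scaf["start"].to_numpy() - d["end"],
                       d["start"] - g_scaf["end"].to_numpy()), 0)
        j = int(np.argmin(gaps))
        rec["nearest_gene"] = g_scaf["gene_id"].iloc[j]
        rec["distance"] = int(gaps[j])
        for w in windows:
            rec[f"genes_within_{w}"] = int(np.sum(gaps <= w))
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence-level annotation
# ---------------------------------------------------------------------------

def gc_content(genome: GenomeIndex, scaffold: str, start: int, end: int) -> float:
    """(G+C) / non-N length of an interval; NaN when the interval is all N."""
    seq = genome.sequence(scaffold)
    if start < 0 or end > len(seq) or end <= start:
        raise ValueError(
            f"interval [{start},{end}) outside scaffold {scaffold} "
            f"(length {len(seq)})")
    window = seq[start:end].upper()
    informative = sum(window.count(b) for b in "ACGT")
    if informative == 0:
        return float("nan")
    return (window.count("G") + window.count("C")) / informative


_BASES = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class PWM:
    """Log-odds position weight matrix built from JASPAR-style counts.

    Counts get a total pseudocount of 0.8 split by the uniform background
    (0.25 per base); weights are log2 odds against that background.  Only
    the relative score ordering matters for the >90% hit rule.
    """

    matrix: np.ndarray  # 4 x L, rows in A,C,G,T order
    pwm_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A,C,G,T)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PWM entries must be finite")

    def __len__(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray, pwm_id: str = "", name: str = "",
                    pseudocount: float = 0.8) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=0)
        probs = (counts + pseudocount * 0.25) / (totals + pseudocount)
        return cls(np.log2(probs / 0.25), pwm_id=pwm_id, name=name)

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1], pwm_id=self.pwm_id, name=self.name)


def read_jaspar(path) -> list[PWM]:
    """Read JASPAR-format PFMs (via Bio.motifs) into log-odds PWMs."""
    from Bio import motifs

    pwms = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in _BASES], dtype=float)
            pwms.append(PWM.from_counts(counts, pwm_id=m.matrix_id or "",
                                        name=m.name or ""))
    return pwms


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    L = len(pwm)
    n_win = len(codes) - L + 1
    scores = np.full(n_win, np.nan)
    if n_win <= 0:
        return scores
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    if valid.any():
        idx = windows[valid]
        scores[valid] = pwm.matrix[idx, np.arange(L)].sum(axis=1)
    return scores


def pwm_scan(sequence: str, pwm: PWM,
             min_rel_score: float = 0.90) -> pd.DataFrame:
    """Scan both strands; a hit is a window with relative score > threshold.

    Relative score = (score - min possible) / (max - min possible), per
    window.  Windows containing N are skipped.  Positions are 0-based
    starts of the window on the forward strand.
    """
    if len(sequence) < len(pwm):
        raise ValueError("sequence shorter than the PWM")
    codes = _encode(sequence)
    lo = pwm.matrix.min(axis=0).sum()
    hi = pwm.matrix.max(axis=0).sum()
    span = hi - lo if hi > lo else 1.0
    rows = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _scan_one_strand(codes, mat)
        rel = (scores - lo) / span
        for p in np.flatnonzero(rel > min_rel_score):
            rows.append((int(p), strand, float(rel[p])))
    return (pd.DataFrame(rows, columns=["position", "strand", "rel_score"])
              .sort_values(["position", "strand"]).reset_index(drop=True))


def pwm_scan_interval(genome: GenomeIndex, scaffold: str, start: int, end: int,
                      pwm: PWM, min_rel_score: float = 0.90,
                      cnes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Scan a genomic interval; hits overlapping a CNE are flagged
    higher-confidence."""
    hits = pwm_scan(genome.sequence(scaffold)[start:end], pwm,
                    min_rel_score=min_rel_score)
    hits["position"] += start
    if cnes is not None and len(hits):
        cn = cnes[cnes["scaffold"] == scaffold]
        flags = []
        for _, h in hits.iterrows():
            h0, h1 = h["position"], h["position"] + len(pwm)
            flags.append(bool(((cn["start"] < h1) & (cn["end"] > h0)).any()))
        hits["high_confidence"] = flags
    elif len(hits):
        hits["high_confidence"] = False
    return hits
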