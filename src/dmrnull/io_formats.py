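"""Readers/writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open ``[start, end)``.  GFF3 is
converted from/to its native 1-based closed convention at the boundary; BED
is native.  CpG positions refer to the C of the plus-strand CpG after
strand combination and are stored 1-based, matching methratio output; they
are shifted to 0-based only when intersected with intervals.

The central in-memory containers are plain :class:`pandas.DataFrame` objects
with documented schemas:

* **CpG table** — columns ``scaffold``, ``pos`` (1-based int), then for each
  sample ``s`` the pair ``meth_<s>`` and ``total_<s>`` (read counts).  A
  locus absent from a sample carries ``total = 0`` (never imputed).
* **DMR table** — see :mod:`dmrnull.dmr_detection`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeIndex",
    "Design",
    "CoverageEstimate",
    "estimate_coverage",
    "read_methratio",
    "write_methratio",
    "merge_samples",
    "sample_ids",
    "read_cpg_table",
    "write_cpg_table",
    "read_features",
    "read_bed",
    "write_bed",
    "write_gff3",
]

METHRATIO_COLUMNS = [
    "chr", "pos", "strand", "context", "ratio", "eff_CT_count",
    "C_count", "CT_count", "rev_G_count", "rev_GA_count",
    "CI_lower", "CI_upper",
]


# ---------------------------------------------------------------------------
# genome index
# ---------------------------------------------------------------------------

@dataclass
class GenomeIndex:
    """Scaffold identities and lengths, optionally with sequence.

    The genome this pipeline targets is highly fragmented (thousands of
    scaffolds, median a few kb), so the index is the shared registry used
    by smoothing, null-interval sampling and annotation.
    """

    lengths: dict[str, int]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"scaffold {name!r} has non-positive length {length}")
        if self.sequences is not None:
            for name, seq in self.sequences.items():
                if name in self.lengths and len(seq) != self.lengths[name]:
                    raise ValueError(f"sequence length mismatch for scaffold {name!r}")

    @property
    def scaffolds(self) -> list[str]:
        return list(self.lengths)

    def __len__(self) -> int:
        return len(self.lengths)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def sequence(self, name: str) -> str:
        if self.sequences is None or name not in self.sequences:
            raise KeyError(f"no sequence stored for scaffold {name!r}")
        return self.sequences[name]

    @classmethod
    def from_fasta(cls, path: str | Path, keep_sequence: bool = True) -> "GenomeIndex":
        from Bio import SeqIO

        lengths: dict[str, int] = {}
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in lengths:
                raise ValueError(f"duplicate scaffold id {rec.id!r} in {path}")
            lengths[rec.id] = len(rec.seq)
            if keep_sequence:
                seqs[rec.id] = str(rec.seq).upper()
        return cls(lengths, seqs if keep_sequence else None)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeIndex":
        df = pd.read_csv(path, sep="\t", names=["scaffold", "length"], header=None,
                         comment="#", dtype={"scaffold": str})
        if df["scaffold"].duplicated().any():
            raise ValueError("duplicate scaffold ids in length table")
        return cls(dict(zip(df["scaffold"], df["length"].astype(int))))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        if self.sequences is None:
            raise ValueError("no sequences stored")
        with open(path, "w") as fh:
            for name in self.lengths:
                seq = self.sequences[name]
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Design:
    """Two-group sample design (paper groups: ND = group1, D = group2)."""

    group1: tuple[str, ...]
    group2: tuple[str, ...]
    labels: tuple[str, str] = ("ND", "D")

    def __init__(self, group1: Sequence[str], group2: Sequence[str],
                 labels: Sequence[str] = ("ND", "D")) -> None:
        object.__setattr__(self, "group1", tuple(group1))
        object.__setattr__(self, "group2", tuple(group2))
        object.__setattr__(self, "labels", tuple(labels))
        if len(self.group1) < 2 or len(self.group2) < 2:
            raise ValueError("need >=2 samples per group for variance estimation")
        if set(self.group1) & set(self.group2):
            raise ValueError("a sample cannot belong to both groups")
        if len(self.labels) != 2:
            raise ValueError("exactly two group labels required")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.group1 + self.group2

    def group_of(self, sample: str) -> str:
        if sample in self.group1:
            return self.labels[0]
        if sample in self.group2:
            return self.labels[1]
        raise KeyError(sample)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Design":
        """Read a two-column TSV: sample_id <tab> group_label."""
        df = pd.read_csv(path, sep="\t", names=["sample", "group"], header=None,
                         comment="#", dtype=str)
        groups = df.groupby("group", sort=True)["sample"].apply(list)
        if len(groups) != 2:
            raise ValueError(f"expected exactly two groups, got {list(groups.index)}")
        labels = tuple(groups.index)
        return cls(groups.iloc[0], groups.iloc[1], labels=labels)


# ---------------------------------------------------------------------------
# coverage QC arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageEstimate:
    read_pairs: float
    effective_read_length: float
    mapped_fraction: float
    genome_length: float

    @property
    def fold_coverage(self) -> float:
        return (self.read_pairs * self.effective_read_length *
                self.mapped_fraction / self.genome_length)


def estimate_coverage(read_pairs: float, read_length: float,
                      mapped_fraction: float, genome_length: float) -> float:
    """Back-of-the-envelope fold coverage: reads x length x mapped / genome.

    With the study's own inputs (125e6 pairs, 95 bp effective read length
    after end-trimming, 56.9% properly mapped, 831 Mb genome) this gives
    ~8x, the usual sanity check before regional smoothing.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if read_pairs <= 0 or read_length <= 0:
        raise ValueError("read_pairs and read_length must be positive")
    if not (0 < mapped_fraction <= 1):
        raise ValueError("mapped_fraction must be in (0, 1]")
    return CoverageEstimate(read_pairs, read_length, mapped_fraction,
                            genome_length).fold_coverage


# ---------------------------------------------------------------------------
# methratio tables
# ---------------------------------------------------------------------------

def _is_cpg_context(context: str) -> bool:
    return "CG" in context.upper()


def read_methratio(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read one methratio-style TSV into a single-sample count column.

    Expects tab-separated columns ``chr pos strand context ratio
    eff_CT_count C_count CT_count [extras...]`` with an optional header
    line.  Only ``chr``, ``pos``, ``context``, ``C_count`` and ``CT_count``
    are consumed; the pre-computed ratio column is ignored because
    smoothing needs the raw counts.  Non-CpG contexts and zero-coverage
    loci are skipped.
    """
    rows: list[tuple[str, int, int, int]] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"chr", "chrom", "chromosome"}:
                continue
            if len(parts) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected >=8 tab-separated fields, got {len(parts)}")
            try:
                scaffold = parts[0]
                pos = int(parts[1])
                context = parts[3]
                c_count = int(round(float(parts[6])))
                ct_count = int(round(float(parts[7])))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
            if not _is_cpg_context(context):
                continue
            if ct_count == 0:
                continue  # no coverage: ratio undefined
            if c_count < 0 or c_count > ct_count:
                raise ValueError(
                    f"{path}:{lineno}: C_count {c_count} outside [0, CT_count={ct_count}]")
            key = (scaffold, pos)
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate locus {key}")
            seen.add(key)
            rows.append((scaffold, pos, c_count, ct_count))
    df = pd.DataFrame(rows, columns=["scaffold", "pos",
                                     f"meth_{sample_id}", f"total_{sample_id}"])
    return df.sort_values(["scaffold", "pos"], kind="mergesort").reset_index(drop=True)


def write_methratio(df: pd.DataFrame, sample_id: str, path: str | Path) -> None:
    """Write one sample's counts as a methratio-style TSV (with header)."""
    meth = df[f"meth_{sample_id}"].to_numpy()
    total = df[f"total_{sample_id}"].to_numpy()
    with open(path, "w") as fh:
        fh.write("\t".join(METHRATIO_COLUMNS) + "\n")
        for scaf, pos, m, t in zip(df["scaffold"], df["pos"], meth, total):
            if t == 0:
                continue
            ratio = m / t
            fh.write(f"{scaf}\t{pos}\t+\tCG\t{ratio:.3f}\t{t:.2f}\t{m}\t{t}"
                     f"\t0\t0\t{max(ratio - 0.1, 0.0):.3f}\t{min(ratio + 0.1, 1.0):.3f}\n")


def sample_ids(cpg_table: pd.DataFrame) -> list[str]:
    """Sample ids present in a CpG table (from its ``meth_*`` columns)."""
    return [c[len("meth_"):] for c in cpg_table.columns if c.startswith("meth_")]


def merge_samples(columns: Sequence[pd.DataFrame], design: Design) -> pd.DataFrame:
    """Align per-sample count columns into one multi-sample CpG table.

    The output locus set is the union of the inputs'; a sample missing a
    locus gets ``meth = total = 0`` so the downstream coverage filter can
    handle it.
    """
    if len(columns) == 0:
        raise ValueError("no sample columns given")
    have = set()
    for col in columns:
        have.update(sample_ids(col))
    missing = [s for s in design.samples if s not in have]
    if missing:
        raise ValueError(f"design samples missing a count column: {missing}")

    merged: pd.DataFrame | None = None
    for col in columns:
        col = col.set_index(["scaffold", "pos"])
        merged = col if merged is None else merged.join(col, how="outer")
    assert merged is not None
    merged = merged.fillna(0).astype(int).reset_index()
    merged["scaffold"] = merged["scaffold"].astype(str)
    merged = merged.sort_values(["scaffold", "pos"], kind="mergesort").reset_index(drop=True)
    ordered = ["scaffold", "pos"]
    for s in design.samples:
        ordered += [f"meth_{s}", f"total_{s}"]
    extras = [c for c in merged.columns if c not in ordered]
    return merged[ordered + extras]


def read_cpg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
    return df


def write_cpg_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / GFF3 features
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a (scaffold, start, end[, name]) frame.

    BED is natively 0-based half-open, matching the internal convention.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with <3 fields")
            name = parts[3] if len(parts) > 3 else f"feat{lineno}"
            start, end = int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty/negative interval")
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path: str | Path,
              score: str | None = None, strand: str | None = None) -> None:
    cols = ["scaffold", "start", "end"]
    out = df[cols].copy()
    out["name"] = df["name"] if "name" in df else [f"feat{i}" for i in range(len(df))]
    if score is not None:
        out["score"] = df[score]
        if strand is not None:
            out["strand"] = df[strand]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_features(gff3_path: str | Path,
                  te_bed: str | Path | None = None,
                  cne_bed: str | Path | None = None):
    """Parse GFF3 gene models (+ optional TE/CNE BED tracks) into a FeatureSet.

    GFF3 coordinates (1-based closed) are shifted to the internal 0-based
    half-open convention.  Introns are derived as the gaps between each
    transcript's exons; an exon is flagged coding when it overlaps a CDS
    record of its transcript.  Children extending outside their parent span
    are clamped with a warning; an unknown strand is an error.
    """
    import gffutils

    from .annotation import FeatureSet

    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")

    gene_rows, exon_rows, intron_rows = [], [], []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise ValueError(f"gene {gene.id}: unknown strand {gene.strand!r}")
        g_start, g_end = gene.start - 1, gene.end
        biotype = (gene.attributes.get("gene_biotype", [""])[0] or
                   gene.attributes.get("biotype", [""])[0])
        transcripts = list(db.children(gene, level=1))
        transcripts = [t for t in transcripts
                       if t.featuretype in ("mRNA", "transcript", "lnc_RNA", "lncRNA")]
        is_lnc = biotype in ("lncRNA", "lnc_RNA") or (
            transcripts and all(t.featuretype in ("lnc_RNA", "lncRNA")
                                for t in transcripts))
        any_cds = False
        for tr in transcripts:
            exons = sorted(db.children(tr, featuretype="exon"),
                           key=lambda f: f.start)
            cds = [(c.start - 1, c.end) for c in db.children(tr, featuretype="CDS")]
            any_cds = any_cds or bool(cds)
            spans = []
            for ex in exons:
                s, e = ex.start - 1, ex.end
                if s < g_start or e > g_end:
                    warnings.warn(
                        f"exon of {tr.id} outside gene span; clamped", stacklevel=2)
                    s, e = max(s, g_start), min(e, g_end)
                coding = any(s < ce and cs < e for cs, ce in cds)
                spans.append((s, e, coding))
                exon_rows.append((gene.id, tr.id, gene.seqid, s, e,
                                  gene.strand, coding))
            for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
                if s2 > e1:
                    intron_rows.append((gene.id, tr.id, gene.seqid, e1, s2,
                                        gene.strand))
        gene_rows.append((gene.id, gene.seqid, g_start, g_end, gene.strand,
                          any_cds, bool(is_lnc), max(len(transcripts), 1)))

    genes = pd.DataFrame(gene_rows, columns=[
        "gene_id", "scaffold", "start", "end", "strand",
        "coding", "lncrna", "n_isoforms"])
    exons = pd.DataFrame(exon_rows, columns=[
        "gene_id", "transcript_id", "scaffold", "start", "end", "strand", "coding"])
    introns = pd.DataFrame(intron_rows, columns=[
        "gene_id", "transcript_id", "scaffold", "start", "end", "strand"])
    tes = read_bed(te_bed) if te_bed is not None else None
    cnes = read_bed(cne_bed) if cne_bed is not None else None
    return FeatureSet(genes=genes, exons=exons, introns=introns,
                      tes=tes, cnes=cnes)


def write_gff3(feature_set, path: str | Path) -> None:
    """Write a FeatureSet's gene models back out as GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        exons = feature_set.exons
        for _, g in feature_set.genes.iterrows():
            biotype = "lncRNA" if g.lncrna else "protein_coding"
            fh.write(f"{g.scaffold}\tdmrnull\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};gene_biotype={biotype}\n")
            g_ex = exons[exons.gene_id == g.gene_id]
            for tr_id, tr_ex in g_ex.groupby("transcript_id", sort=True):
                ftype = "lnc_RNA" if g.lncrna else "mRNA"
                t_start, t_end = tr_ex.start.min(), tr_ex.end.max()
                fh.write(f"{g.scaffold}\tdmrnull\t{ftype}\t{t_start + 1}\t{t_end}"
                         f"\t.\t{g.strand}\t.\tID={tr_id};Parent={g.gene_id}\n")
                for i, (_, ex) in enumerate(tr_ex.sort_values("start").iterrows()):
                    fh.write(f"{g.scaffold}\tdmrnull\texon\t{ex.start + 1}\t{ex.end}"
                             f"\t.\t{g.strand}\t.\tID={tr_id}.e{i};Parent={tr_id}\n")
                    if ex.coding:
                        fh.write(f"{g.scaffold}\tdmrnull\tCDS\t{ex.start + 1}\t"
                                 f"{ex.end}\t.\t{g.strand}\t0\t"
                                 f"ID={tr_id}.c{i};Parent={tr_id}\n")
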