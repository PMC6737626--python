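"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the structure of a fragmented teleost methylome
study without any download: a scaffolded genome whose lengths are
log-normal with a ~5 kb median plus a handful of explicitly long scaffolds
(the heavy right tail, scaled to desk size); CpGs placed at a background
density of ~1 per 50 bp with CpG-island-like dense blocks where DMRs are
planted (vertebrate DMRs concentrate at CpG-rich regulatory elements, and
per-scaffold quantile cutoffs only make sense when a DMR is a small
fraction of its scaffold's CpGs); two groups of two samples with
negative-binomial coverage (mean ~21x) and binomial methylated counts
around a logit-space AR(1) baseline field with genome-wide mean ~0.85;
planted DMRs of 100-2000 bp whose group means differ by 0.1-0.4 around a
~0.6 local baseline; gene/TE/CNE/lncRNA annotation tracks; and optional
single-sample outlier blocks for exercising the label-shuffle filter.

Everything is driven by one :class:`numpy.random.Generator`, so a fixed
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import FeatureSet
from .io_formats import Design, GenomeIndex, merge_samples, write_methratio

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_methylome",
    "simulate_expression",
    "simulate_dataset",
    "evaluate_recovery",
]

_LOGIT = lambda p: np.log(p / (1.0 - p))
_EXPIT = lambda x: 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator (defaults = emulated study)."""

    # genome structure
    n_scaffolds: int = 40
    scaffold_length_median: float = 5000.0
    scaffold_length_sigma: float = 1.0
    n_large_scaffolds: int = 6          # explicit heavy right tail
    large_scaffold_length: int = 120_000
    gc_background: float = 0.40
    cpg_density: float = 0.02           # ~1 CpG per 50 bp outside islands
    island_cpg_density: float = 0.08    # within planted DMR blocks
    island_margin_bp: int = 1000        # island extends past the differential
                                        # region: boundaries are measurable

    # annotation densities (features per bp)
    gene_density: float = 1.0 / 20_000
    gene_length_range: tuple[int, int] = (1000, 8000)
    lncrna_fraction: float = 0.15
    antisense_pair_rate: float = 0.5
    te_density: float = 1.0 / 5000
    te_width_range: tuple[int, int] = (100, 1500)
    cne_density: float = 1.0 / 10_000
    cne_width_range: tuple[int, int] = (50, 300)

    # methylome
    n_samples_per_group: int = 2
    coverage_mean: float = 21.0
    coverage_dispersion: float = 5.0    # NB size parameter
    baseline_mean: float = 0.85         # genome-wide methylation level
    baseline_logit_sd: float = 0.6
    baseline_logit_rho: float = 0.98    # AR(1) over CpG index
    sample_logit_sd: float = 0.15       # smooth per-sample deviation field
    sample_logit_rho: float = 0.9

    # planted DMRs
    n_dmrs: int = 8
    dmr_width_range: tuple[int, int] = (100, 2000)
    dmr_delta_range: tuple[float, float] = (0.1, 0.4)
    dmr_baseline_mean: float = 0.60     # local baseline inside DMR blocks
    direction_mix: float = 0.5          # fraction D-higher
    dmr_min_separation: int = 2000      # >> call-time maxGap: truth unambiguous
    n_subthreshold_dmrs: int = 0        # decoys with delta below 0.1
    subthreshold_delta: float = 0.05

    # single-sample outlier blocks (group signal absent)
    n_outlier_blocks: int = 0
    outlier_delta: float = 0.5

    # expression
    tpm_log_mean: float = np.log(10.0)
    tpm_log_sd: float = 1.2
    tpm_noise_sd: float = 0.15
    expression_coupling: float = -1.0   # sign linking DMR direction to log2fc


@dataclass
class TruthSet:
    """Planted ground truth: DMR intervals, outlier blocks, expression."""

    dmrs: pd.DataFrame          # scaffold,start,end,width,delta,direction,detectable
    outliers: pd.DataFrame      # scaffold,start,end,sample,delta
    expression: pd.DataFrame | None = None  # gene_id, planted_log2fc


@dataclass
class SimulatedDataset:
    genome: GenomeIndex
    features: FeatureSet
    counts: pd.DataFrame
    design: Design
    truth: TruthSet
    cpg_positions: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _scaffold_lengths(config: SimulationConfig, rng: np.random.Generator) -> dict[str, int]:
    n_small = config.n_scaffolds - config.n_large_scaffolds
    if n_small < 0:
        raise ValueError("n_large_scaffolds exceeds n_scaffolds")
    small = rng.lognormal(np.log(config.scaffold_length_median),
                          config.scaffold_length_sigma, size=n_small)
    lengths = [int(max(x, 500)) for x in small]
    lengths += [int(config.large_scaffold_length *
                    rng.uniform(0.8, 1.4)) for _ in range(config.n_large_scaffolds)]
    rng.shuffle(lengths)
    return {f"scaffold_{i}": L for i, L in enumerate(lengths)}


def _plant_blocks(lengths: dict[str, int], n_blocks: int,
                  width_range: tuple[int, int], min_sep: int,
                  rng: np.random.Generator,
                  occupied: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Non-overlapping blocks spread round-robin over the largest scaffolds.

    Spreading keeps any one scaffold's share of planted CpGs small, the
    regime the per-scaffold quantile cutoffs are designed for (real DMRs
    are a tiny fraction of any scaffold).
    """
    hosts = sorted(lengths, key=lengths.get, reverse=True)
    n_hosts = max(1, min(len(hosts), 8))
    placed = []
    for b in range(n_blocks):
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        for _attempt in range(200):
            scaf = hosts[(b + _attempt) % n_hosts]
            L = lengths[scaf]
            if L < width + 2 * min_sep:
                continue
            start = int(rng.integers(min_sep, L - width - min_sep))
            clash = any(s == scaf and start - min_sep < e and st < start + width + min_sep
                        for s, st, e in occupied + placed)
            if not clash:
                placed.append((scaf, start, start + width))
                break
        else:
            raise RuntimeError("could not place all blocks; densities too high")
    return placed


def _build_sequence(length: int, blocks: list[tuple[int, int]],
                    config: SimulationConfig, rng: np.random.Generator) -> str:
    """Random nucleotides with CpG sites at background density, denser
    inside the given blocks."""
    gc = config.gc_background
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(np.array(list("ACGT")), size=length, p=probs)
    # knock out incidental CpGs so density is controlled
    cg = np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G"))
    seq[cg] = "A"
    dens = np.full(length, config.cpg_density)
    for s, e in blocks:
        dens[s:e] = config.island_cpg_density
    sites = np.flatnonzero(rng.random(length - 1) < dens[:-1])
    keep = [s for i, s in enumerate(sites) if i == 0 or s - sites[i - 1] >= 2]
    for s in keep:
        seq[s] = "C"
        seq[s + 1] = "G"
    return "".join(seq)


def _place_genes(lengths: dict[str, int], config: SimulationConfig,
                 rng: np.random.Generator) -> FeatureSet:
    gene_rows, exon_rows, intron_rows = [], [], []
    te_rows, cne_rows = [], []
    gid = 0
    coding_genes: list[tuple[str, int, int, str]] = []
    for scaf, L in lengths.items():
        n_genes = rng.poisson(config.gene_density * L)
        for _ in range(n_genes):
            glen = int(rng.integers(*config.gene_length_range))
            if glen >= L:
                continue
            start = int(rng.integers(0, L - glen))
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            is_lnc = rng.random() < config.lncrna_fraction
            if is_lnc and coding_genes and rng.random() < config.antisense_pair_rate:
                host = coding_genes[int(rng.integers(0, len(coding_genes)))]
                h_scaf, h_start, h_end, h_strand = host
                if h_end - h_start > 600:
                    scaf_g = h_scaf
                    glen = min(glen, (h_end - h_start) - 200)
                    start = int(rng.integers(h_start, h_end - glen))
                    end = start + glen
                    strand = "-" if h_strand == "+" else "+"
                else:
                    scaf_g = scaf
            else:
                scaf_g = scaf
            gene_id = f"gene_{gid}"
            gid += 1
            n_iso = 1 + min(int(rng.poisson(0.8)), 9)
            n_ex = int(rng.integers(2, 7))
            cuts = np.sort(rng.choice(
                np.arange(1, glen // 100 or 2), size=min(2 * n_ex - 2, max(glen // 100 - 1, 1)),
                replace=False)) * 100 if glen >= 300 else np.array([], dtype=int)
            bounds = [0] + list(cuts[:2 * n_ex - 2]) + [glen]
            exons = [(start + bounds[i], start + bounds[i + 1])
                     for i in range(0, len(bounds) - 1, 2)]
            if not exons:
                exons = [(start, end)]
            for iso in range(n_iso):
                tr_id = f"{gene_id}.t{iso}"
                iso_ex = list(exons)
                if iso > 0 and len(iso_ex) > 2:
                    drop = int(rng.integers(1, len(iso_ex) - 1))
                    iso_ex = iso_ex[:drop] + iso_ex[drop + 1:]
                for k_e, (es, ee) in enumerate(iso_ex):
                    # coding except terminal UTR exons (lncRNAs never code)
                    coding = (not is_lnc) and 0 < k_e < len(iso_ex) - 1 or \
                        (not is_lnc and len(iso_ex) <= 2 and k_e == 0)
                    exon_rows.append((gene_id, tr_id, scaf_g, es, ee, strand,
                                      bool(coding)))
                for (e1s, e1e), (e2s, e2e) in zip(iso_ex, iso_ex[1:]):
                    if e2s > e1e:
                        intron_rows.append((gene_id, tr_id, scaf_g, e1e, e2s, strand))
            gene_rows.append((gene_id, scaf_g, start, end, strand,
                              not is_lnc, is_lnc, n_iso))
            if not is_lnc:
                coding_genes.append((scaf_g, start, end, strand))
        for _ in range(rng.poisson(config.te_density * L)):
            w = int(rng.integers(*config.te_width_range))
            if w < L:
                s = int(rng.integers(0, L - w))
                te_rows.append((scaf, s, s + w, f"te_{len(te_rows)}"))
        for _ in range(rng.poisson(config.cne_density * L)):
            w = int(rng.integers(*config.cne_width_range))
            if w < L:
                s = int(rng.integers(0, L - w))
                cne_rows.append((scaf, s, s + w, f"cne_{len(cne_rows)}"))
    genes = pd.DataFrame(gene_rows, columns=[
        "gene_id", "scaffold", "start", "end", "strand", "coding", "lncrna",
        "n_isoforms"])
    exons = pd.DataFrame(exon_rows, columns=[
        "gene_id", "transcript_id", "scaffold", "start", "end", "strand", "coding"])
    introns = pd.DataFrame(intron_rows, columns=[
        "gene_id", "transcript_id", "scaffold", "start", "end", "strand"])
    tes = pd.DataFrame(te_rows, columns=["scaffold", "start", "end", "name"])
    cnes = pd.DataFrame(cne_rows, columns=["scaffold", "start", "end", "name"])
    return FeatureSet(genes=genes, exons=exons, introns=introns,
                      tes=tes, cnes=cnes)


def simulate_genome(config: SimulationConfig, rng: np.random.Generator
                    ) -> tuple[GenomeIndex, FeatureSet, TruthSet, dict[str, np.ndarray]]:
    """Scaffolded genome with CpG-dense planted blocks plus annotations.

    Returns the genome index (with sequence), the feature tracks, the truth
    set (planted DMRs with delta/direction, outlier blocks) and the per-
    scaffold CpG position arrays (0-based C positions).
    """
    lengths = _scaffold_lengths(config, rng)
    dmr_blocks = _plant_blocks(lengths, config.n_dmrs, config.dmr_width_range,
                               config.dmr_min_separation, rng, [])
    decoy_blocks = _plant_blocks(lengths, config.n_subthreshold_dmrs,
                                 config.dmr_width_range,
                                 config.dmr_min_separation, rng, dmr_blocks)
    outlier_blocks = _plant_blocks(lengths, config.n_outlier_blocks,
                                   config.dmr_width_range,
                                   config.dmr_min_separation, rng,
                                   dmr_blocks + decoy_blocks)

    deltas = rng.uniform(*config.dmr_delta_range, size=config.n_dmrs)
    dirs = np.where(rng.random(config.n_dmrs) < config.direction_mix,
                    "D-higher", "ND-higher")
    truth_rows = [
        {"scaffold": s, "start": st, "end": e, "width": e - st,
         "delta": float(d), "direction": di, "detectable": True}
        for (s, st, e), d, di in zip(dmr_blocks, deltas, dirs)]
    truth_rows += [
        {"scaffold": s, "start": st, "end": e, "width": e - st,
         "delta": config.subthreshold_delta,
         "direction": "D-higher" if rng.random() < 0.5 else "ND-higher",
         "detectable": False}
        for (s, st, e) in decoy_blocks]
    truth_dmrs = pd.DataFrame(
        truth_rows, columns=["scaffold", "start", "end", "width", "delta",
                             "direction", "detectable"])
    samples = ([f"ND{i + 1}" for i in range(config.n_samples_per_group)] +
               [f"D{i + 1}" for i in range(config.n_samples_per_group)])
    outlier_rows = [
        {"scaffold": s, "start": st, "end": e,
         "sample": samples[int(rng.integers(0, len(samples)))],
         "delta": config.outlier_delta}
        for (s, st, e) in outlier_blocks]
    outliers = pd.DataFrame(outlier_rows,
                            columns=["scaffold", "start", "end", "sample", "delta"])

    blocks_by_scaf: dict[str, list[tuple[int, int]]] = {}
    m = config.island_margin_bp
    for s, st, e in dmr_blocks + decoy_blocks + outlier_blocks:
        blocks_by_scaf.setdefault(s, []).append((max(st - m, 0), e + m))
    sequences = {}
    cpg_positions = {}
    for scaf, L in lengths.items():
        seq = _build_sequence(L, blocks_by_scaf.get(scaf, []), config, rng)
        sequences[scaf] = seq
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        cpg_positions[scaf] = np.flatnonzero((arr[:-1] == ord("C")) &
                                             (arr[1:] == ord("G")))
    genome = GenomeIndex(lengths, sequences)
    features = _place_genes(lengths, config, rng)
    return genome, features, TruthSet(dmrs=truth_dmrs, outliers=outliers), cpg_positions


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _ar1(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd``."""
    x = np.empty(n)
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return x


def simulate_methylome(genome_truth: tuple, config: SimulationConfig,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, Design]:
    """Per-CpG binomial counts for a 2v2 (configurable) design.

    True levels follow the baseline AR(1) logit field, recentered to
    ~``dmr_baseline_mean`` inside planted blocks and split by ±delta/2
    between groups; outlier blocks shift one sample only.
    """
    genome, _features, truth, cpg_positions = genome_truth
    n_per = config.n_samples_per_group
    nd = [f"ND{i + 1}" for i in range(n_per)]
    dd = [f"D{i + 1}" for i in range(n_per)]
    design = Design(nd, dd)
    samples = design.samples
    mu0 = _LOGIT(config.baseline_mean)
    mu_dmr = _LOGIT(config.dmr_baseline_mean)
    frames = []
    for scaf in genome.scaffolds:
        pos0 = cpg_positions[scaf]
        n = len(pos0)
        if n == 0:
            continue
        base_logit = mu0 + _ar1(n, config.baseline_logit_sd,
                                config.baseline_logit_rho, rng)
        in_block = np.zeros(n, dtype=bool)
        group_shift = np.zeros(n)  # added to D, subtracted from ND (prob scale)
        t_scaf = truth.dmrs[truth.dmrs["scaffold"] == scaf]
        for _, b in t_scaf.iterrows():
            mask = (pos0 >= b["start"]) & (pos0 < b["end"])
            in_block |= mask
            sign = 1.0 if b["direction"] == "D-higher" else -1.0
            group_shift[mask] = sign * b["delta"] / 2.0
        base_logit = np.where(in_block, base_logit - mu0 + mu_dmr, base_logit)
        p_base = _EXPIT(base_logit)
        p_nd = np.clip(p_base - group_shift, 0.001, 0.999)
        p_d = np.clip(p_base + group_shift, 0.001, 0.999)
        o_scaf = truth.outliers[truth.outliers["scaffold"] == scaf]
        data = {"scaffold": scaf, "pos": pos0 + 1}
        for s in samples:
            p = p_d.copy() if s in dd else p_nd.copy()
            for _, ob in o_scaf.iterrows():
                if ob["sample"] == s:
                    mask = (pos0 >= ob["start"]) & (pos0 < ob["end"])
                    p[mask] = np.clip(p[mask] - ob["delta"], 0.001, 0.999)
            noise = _ar1(n, config.sample_logit_sd, config.sample_logit_rho, rng)
            p_s = np.clip(_EXPIT(_LOGIT(p) + noise), 1e-4, 1 - 1e-4)
            # NB(mean, size): gamma-Poisson mixture
            lam = rng.gamma(config.coverage_dispersion,
                            config.coverage_mean / config.coverage_dispersion,
                            size=n)
            total = rng.poisson(lam)
            meth = rng.binomial(total, p_s)
            data[f"meth_{s}"] = meth
            data[f"total_{s}"] = total
        frames.append(pd.DataFrame(data))
    counts = pd.concat(frames, ignore_index=True)
    counts = counts.sort_values(["scaffold", "pos"], kind="mergesort").reset_index(drop=True)
    return counts, design


def write_methratio_files(counts: pd.DataFrame, design: Design,
                          out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in design.samples:
        p = out_dir / f"{s}.methratio.tsv"
        write_methratio(counts, s, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(features: FeatureSet, truth: TruthSet,
                        config: SimulationConfig, rng: np.random.Generator,
                        design: Design) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample TPM table with expression effects coupled to planted DMRs.

    Genes overlapping (or flanked within 5 kb by) a planted DMR receive a
    log2 fold-change ``coupling * direction * 2 * delta`` so that
    methylation-expression correlation analyses have recoverable signal;
    all genes get log-normal baselines and mild per-sample noise.
    """
    genes = features.genes
    baseline = rng.lognormal(config.tpm_log_mean, config.tpm_log_sd,
                             size=len(genes))
    planted_fc = np.zeros(len(genes))
    for _, t in truth.dmrs[truth.dmrs["detectable"]].iterrows():
        sign = 1.0 if t["direction"] == "D-higher" else -1.0
        near = ((genes["scaffold"] == t["scaffold"]) &
                (genes["start"] - 5000 < t["end"]) &
                (t["start"] < genes["end"] + 5000))
        planted_fc[near.to_numpy()] = config.expression_coupling * sign * 2.0 * t["delta"]
    tpm = pd.DataFrame({"gene_id": genes["gene_id"]})
    for s in design.group1:
        tpm[s] = baseline * rng.lognormal(0.0, config.tpm_noise_sd, len(genes))
    for s in design.group2:
        tpm[s] = baseline * (2.0 ** planted_fc) * rng.lognormal(
            0.0, config.tpm_noise_sd, len(genes))
    truth_expr = pd.DataFrame({"gene_id": genes["gene_id"],
                               "planted_log2fc": planted_fc})
    return tpm, truth_expr


# ---------------------------------------------------------------------------
# one-call dataset + recovery scoring
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int = 0) -> SimulatedDataset:
    """Generate a complete dataset (genome, features, counts, truth)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    genome, features, truth, cpg_positions = simulate_genome(config, rng)
    counts, design = simulate_methylome((genome, features, truth, cpg_positions),
                                        config, rng)
    return SimulatedDataset(genome=genome, features=features, counts=counts,
                            design=design, truth=truth,
                            cpg_positions=cpg_positions)


def evaluate_recovery(called_dmrs: pd.DataFrame, truth: pd.DataFrame,
                      min_reciprocal_overlap: float = 0.5) -> dict:
    """Sensitivity / FDR of called DMRs against planted truth intervals.

    A truth interval is recovered when some called DMR overlaps it by at
    least the threshold fraction of *both* widths with matching direction;
    a called DMR matching no detectable truth interval is a false positive.
    """
    detectable = truth[truth.get("detectable", pd.Series(True, index=truth.index))]
    recovered = np.zeros(len(detectable), dtype=bool)
    called = called_dmrs.reset_index(drop=True)
    matched_call = np.zeros(len(called), dtype=bool)
    per_truth = []
    for ti, (_, t) in enumerate(detectable.iterrows()):
        for ci, (_, c) in enumerate(called.iterrows()):
            if c["scaffold"] != t["scaffold"]:
                continue
            ov = min(c["end"], t["end"]) - max(c["start"], t["start"])
            if ov <= 0:
                continue
            if (ov / (c["end"] - c["start"]) >= min_reciprocal_overlap and
                    ov / (t["end"] - t["start"]) >= min_reciprocal_overlap and
                    ("direction" not in c or c["direction"] == t["direction"])):
                recovered[ti] = True
                matched_call[ci] = True
        per_truth.append({"scaffold": t["scaffold"], "start": t["start"],
                          "end": t["end"], "delta": t.get("delta", np.nan),
                          "width": t["end"] - t["start"],
                          "recovered": bool(recovered[ti])})
    sensitivity = float(recovered.mean()) if len(detectable) else np.nan
    fdr = float((~matched_call).mean()) if len(called) else np.nan
    return {"sensitivity": sensitivity, "fdr": fdr,
            "n_truth": int(len(detectable)), "n_called": int(len(called)),
            "per_truth": pd.DataFrame(per_truth)}
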