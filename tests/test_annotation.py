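import numpy as np
import pandas as pd
import pytest

from dmrnull.annotation import (PWM, classify_regulatory_hits,
                                derive_regulatory_regions, distance_table,
                                gc_content, overlap_table, pwm_scan,
                                pwm_scan_interval, read_jaspar)
from dmrnull.io_formats import GenomeIndex


def dmrs_at(rows):
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


# ---------------------------------------------------------------------------
# regulatory regions
# ---------------------------------------------------------------------------

def test_regulatory_regions_plus_strand():
    five, three = derive_regulatory_regions(10000, 20000, "+")
    assert five == (5000, 11000)
    assert three == (19000, 25000)


def test_regulatory_regions_minus_strand_mirror():
    five, three = derive_regulatory_regions(10000, 20000, "-")
    assert five == (19000, 25000)  # TSS at 20000
    assert three == (5000, 11000)


def test_regulatory_regions_clamped():
    five, _ = derive_regulatory_regions(2000, 9000, "+", scaffold_length=50000)
    assert five == (0, 3000)


# ---------------------------------------------------------------------------
# type-1/2/3 classification
# ---------------------------------------------------------------------------

def iso_hits(hits, gene):
    return hits[hits["gene_id"] == gene]


def test_tss_overlap_is_type2_5p(two_gene_features):
    # DMR overlapping gene C's TSS (first 1 kb): the ubxn4 configuration
    hits = classify_regulatory_hits(dmrs_at([("scaf2", 49800, 50200)]),
                                    two_gene_features)
    c = iso_hits(hits, "C")
    assert set(zip(c["hit_type"], c["side"])) == {(2, "5p")}


def test_3prime_edge_is_type2_3p(two_gene_features):
    hits = classify_regulatory_hits(dmrs_at([("scaf2", 59500, 59900)]),
                                    two_gene_features)
    c = iso_hits(hits, "C")
    assert set(zip(c["hit_type"], c["side"])) == {(2, "3p")}


def test_upstream_no_body_overlap_is_type1(two_gene_features):
    # 3 kb upstream of gene C, outside the body
    hits = classify_regulatory_hits(dmrs_at([("scaf2", 46800, 47000)]),
                                    two_gene_features)
    c = iso_hits(hits, "C")
    assert set(zip(c["hit_type"], c["side"])) == {(1, "5p")}


def test_body_only_no_regulatory_hit(two_gene_features):
    # middle of gene C: body overlap but neither first nor last 1 kb
    hits = classify_regulatory_hits(dmrs_at([("scaf2", 54000, 54500)]),
                                    two_gene_features)
    assert iso_hits(hits, "C").empty


def test_antisense_type3(two_gene_features):
    """A type-2 hit for gene A that sits inside antisense gene B's body is
    also reported type-3 (brute-force geometry on the two-gene fixture)."""
    hits = classify_regulatory_hits(dmrs_at([("scaf1", 9800, 10300)]),
                                    two_gene_features)
    a = iso_hits(hits, "A")
    assert (2, "5p") in set(zip(a["hit_type"], a["side"]))
    t3 = a[a["hit_type"] == 3]
    assert len(t3) == 1 and t3.iloc[0]["antisense_body_gene_id"] == "B"
    # every type-3 hit has an underlying type-1/2 hit for the same gene
    for _, h in hits[hits["hit_type"] == 3].iterrows():
        base = hits[(hits["gene_id"] == h["gene_id"]) &
                    (hits["dmr_index"] == h["dmr_index"]) &
                    (hits["hit_type"].isin([1, 2]))]
        assert len(base) >= 1


def test_type1_excludes_any_body_overlap(two_gene_features):
    # within 5 kb of A but overlapping B's body: type-1 for A only if no
    # body overlap with A itself; B gets no type-1 (body overlap)
    hits = classify_regulatory_hits(dmrs_at([("scaf1", 9000, 9500)]),
                                    two_gene_features)
    a = iso_hits(hits, "A")
    assert set(a[a["hit_type"] == 1]["side"]) == {"5p"}
    b = iso_hits(hits, "B")
    assert (b["hit_type"] != 1).all()


# ---------------------------------------------------------------------------
# overlap / distance tables
# ---------------------------------------------------------------------------

def test_overlap_basics(two_gene_features):
    table = overlap_table(dmrs_at([("scaf1", 100, 200), ("scaf1", 200, 210)]),
                          two_gene_features)
    assert bool(table.iloc[0]["te"]) and table.iloc[0]["te_count"] == 1
    # half-open abutment: TE [200,300) touches DMR [100,200) by zero bp
    assert table.iloc[1]["te_count"] == 1  # [200,210) is inside [200,300)
    t0 = overlap_table(dmrs_at([("scaf1", 100, 200)]), two_gene_features)
    assert t0.iloc[0]["te_count"] == 1  # [150,160) only; [200,300) abuts


def test_overlap_matches_quadratic_oracle(two_gene_features):
    rng = np.random.default_rng(6)
    dmrs = dmrs_at([("scaf1", int(s), int(s) + int(w))
                    for s, w in zip(rng.integers(0, 30000, 40),
                                    rng.integers(10, 2000, 40))])
    table = overlap_table(dmrs, two_gene_features)
    for kind, frame in (("te", two_gene_features.tes),
                        ("cne", two_gene_features.cnes),
                        ("gene_body", two_gene_features.genes)):
        for i, d in dmrs.iterrows():
            n = sum(1 for _, f in frame.iterrows()
                    if f["scaffold"] == d["scaffold"]
                    and max(d["start"], f["start"]) < min(d["end"], f["end"]))
            assert table.loc[i, f"{kind}_count"] == n, (kind, i)


def test_distance_table(two_gene_features):
    genes = two_gene_features.genes
    t = distance_table(dmrs_at([("scaf2", 49800, 49900),
                                ("scaf2", 55000, 55500)]), genes)
    assert t.iloc[0]["distance"] == 100  # gap to gene C at 50000
    assert t.iloc[1]["distance"] == 0    # overlap
    windows = [c for c in t.columns if c.startswith("genes_within_")]
    counts = t[windows].to_numpy()
    assert (np.diff(counts, axis=1) >= 0).all()  # monotone in window

    nog = distance_table(dmrs_at([("scafZ", 0, 100)]), genes)
    assert np.isnan(nog.iloc[0]["distance"])


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def test_gc_content_values():
    gi = GenomeIndex({"s": 16}, {"s": "GCGCATATGCATNNNN"})
    assert gc_content(gi, "s", 0, 4) == 1.0
    assert gc_content(gi, "s", 4, 8) == 0.0
    assert gc_content(gi, "s", 8, 12) == 0.5
    assert np.isnan(gc_content(gi, "s", 12, 16))   # all-N
    assert gc_content(gi, "s", 8, 16) == 0.5       # N excluded from length
    with pytest.raises(ValueError):
        gc_content(gi, "s", 10, 20)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_pwm():
    counts = np.array([
        [8, 0, 0, 2],   # A
        [1, 9, 0, 2],   # C
        [0, 1, 9, 2],   # G
        [1, 0, 1, 4],   # T
    ], dtype=float)
    return PWM.from_counts(counts, pwm_id="toy")


def test_consensus_and_antiinconsensus_windows(toy_pwm):
    consensus = "ACGT"  # per-position argmax
    worst = "GTCA"      # per-position argmin (G has min weight at pos 0? compute)
    mat = toy_pwm.matrix
    best_seq = "".join("ACGT"[i] for i in mat.argmax(axis=0))
    worst_seq = "".join("ACGT"[i] for i in mat.argmin(axis=0))
    hits = pwm_scan(best_seq, toy_pwm, min_rel_score=0.99)
    fw = hits[hits["strand"] == "+"]
    assert len(fw) == 1 and fw.iloc[0]["rel_score"] == pytest.approx(1.0)
    none = pwm_scan(worst_seq, toy_pwm, min_rel_score=0.0)
    fw0 = none[none["strand"] == "+"]
    assert fw0.empty  # rel_score 0.0 is not > 0.0


def test_scan_matches_bruteforce_both_strands(toy_pwm):
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), 12))
    got = pwm_scan(seq, toy_pwm, min_rel_score=0.2)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    mat = toy_pwm.matrix
    lo = mat.min(axis=0).sum()
    hi = mat.max(axis=0).sum()
    expected = []
    for p in range(len(seq) - 4 + 1):
        win = seq[p:p + 4]
        for strand in "+-":
            w = win if strand == "+" else "".join(comp[b] for b in win[::-1])
            score = sum(mat["ACGT".index(b)][i] for i, b in enumerate(w))
            rel = (score - lo) / (hi - lo)
            if rel > 0.2:
                expected.append((p, strand, round(rel, 9)))
    got_t = [(int(r["position"]), r["strand"], round(r["rel_score"], 9))
             for _, r in got.iterrows()]
    assert sorted(got_t) == sorted(expected)


def test_n_windows_skipped(toy_pwm):
    hits = pwm_scan("ACNTACGT", toy_pwm, min_rel_score=0.0)
    assert (hits["position"] >= 3).all()  # windows 0..2 contain the N


def test_jaspar_reader_and_cne_flag(tmp_path, two_gene_features):
    jaspar = ">MA0001.1 toy\nA [ 8 0 0 2 ]\nC [ 1 9 0 2 ]\nG [ 0 1 9 2 ]\nT [ 1 0 1 4 ]\n"
    p = tmp_path / "m.jaspar"
    p.write_text(jaspar)
    pwms = read_jaspar(p)
    assert len(pwms) == 1 and len(pwms[0]) == 4
    seq = "T" * 11000 + "ACGT" + "T" * 5000
    gi = GenomeIndex({"scaf1": len(seq)}, {"scaf1": seq})
    hits = pwm_scan_interval(gi, "scaf1", 10900, 11100, pwms[0],
                             min_rel_score=0.9, cnes=two_gene_features.cnes)
    strong = hits[hits["strand"] == "+"]
    assert len(strong) == 1
    assert int(strong.iloc[0]["position"]) == 11000
    assert bool(strong.iloc[0]["high_confidence"])  # inside CNE [11000,11050)


def test_pwm_validation():
    with pytest.raises(ValueError):
        PWM(np.zeros((3, 4)))
    with pytest.raises(ValueError):
        PWM(np.full((4, 3), np.inf))
    with pytest.raises(ValueError):
        pwm_scan("AC", PWM(np.zeros((4, 4))))
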