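import numpy as np
import pandas as pd
import pytest

from dmrnull.annotation import FeatureSet
from dmrnull.io_formats import Design


@pytest.fixture(scope="session")
def design_2v2() -> Design:
    return Design(["ND1", "ND2"], ["D1", "D2"])


def make_counts(scaffold, positions, meth, total, samples):
    """Build a multi-sample CpG table from per-sample count arrays."""
    data = {"scaffold": scaffold, "pos": np.asarray(positions)}
    for s, m, t in zip(samples, meth, total):
        data[f"meth_{s}"] = np.asarray(m)
        data[f"total_{s}"] = np.asarray(t)
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def two_gene_features() -> FeatureSet:
    """Plus-strand gene A [10000,20000) with antisense gene B [8000,30000)
    plus an isolated gene C, for regulatory-hit geometry tests."""
    genes = pd.DataFrame([
        ("A", "scaf1", 10000, 20000, "+", True, False, 1),
        ("B", "scaf1", 8000, 30000, "-", True, False, 1),
        ("C", "scaf2", 50000, 60000, "+", True, False, 1),
    ], columns=["gene_id", "scaffold", "start", "end", "strand",
                "coding", "lncrna", "n_isoforms"])
    exons = pd.DataFrame([
        ("A", "A.t0", "scaf1", 10000, 12000, "+", False),
        ("A", "A.t0", "scaf1", 15000, 20000, "+", True),
        ("B", "B.t0", "scaf1", 8000, 30000, "-", True),
        ("C", "C.t0", "scaf2", 50000, 60000, "+", True),
    ], columns=["gene_id", "transcript_id", "scaffold", "start", "end",
                "strand", "coding"])
    introns = pd.DataFrame([
        ("A", "A.t0", "scaf1", 12000, 15000, "+"),
    ], columns=["gene_id", "transcript_id", "scaffold", "start", "end", "strand"])
    tes = pd.DataFrame([("scaf1", 150, 160, "te0"), ("scaf1", 200, 300, "te1")],
                       columns=["scaffold", "start", "end", "name"])
    cnes = pd.DataFrame([("scaf1", 11000, 11050, "cne0")],
                        columns=["scaffold", "start", "end", "name"])
    return FeatureSet(genes=genes, exons=exons, introns=introns,
                      tes=tes, cnes=cnes)
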