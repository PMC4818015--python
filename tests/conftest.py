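import numpy as np
import pandas as pd
import pytest

from vocal.benchmark import make_benchmark_inputs
from vocal.core_data import GenotypeMatrix, Locus, ReferenceMatrix


@pytest.fixture(scope="session")
def bench_inputs():
    """Shared synthetic benchmark ingredients (reference, grouping, panel)."""
    return make_benchmark_inputs(seed=1)


@pytest.fixture
def small_reference():
    """5 genes x 4 cell types, 2 replicates each, with clear marker blocks."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(5)]
    cols, rep_map = {}, {}
    for ci, ct in enumerate(["A", "B", "C", "D"]):
        profile = np.full(5, 1.0)
        if ci < 5:
            profile[ci % 5] = 8.0 + ci
        for r in (1, 2):
            col = f"{ct}_r{r}"
            cols[col] = profile + rng.normal(0, 0.05, 5)
            rep_map[col] = ct
    return ReferenceMatrix(pd.DataFrame(cols, index=genes), rep_map)


def make_geno(codes, strains=None, chrom="1"):
    """GenotypeMatrix from a strains x loci array of int codes."""
    codes = np.asarray(codes, dtype=np.int8)
    strains = strains or [f"s{i}" for i in range(codes.shape[0])]
    locus_ids = [f"v{j}" for j in range(codes.shape[1])]
    loci = [Locus(l, chrom, float(j)) for j, l in enumerate(locus_ids)]
    return GenotypeMatrix(pd.DataFrame(codes, index=strains, columns=locus_ids), loci)
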