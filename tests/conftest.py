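"""Shared fixtures: small synthetic studies and hand-built matrices."""

import numpy as np
import pandas as pd
import pytest

from imprintscan.dmr import CpGMethylationMatrix
from imprintscan.simulate import SimConfig, simulate_allelic_counts


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=1, n_genes=300, n_cpgs=4000, n_planted_dmrs=10)


@pytest.fixture(scope="session")
def small_study(small_config):
    table, truth = simulate_allelic_counts(small_config)
    return table, truth


def make_table(per_sample_counts, crosses=None, chrom="chr1"):
    """Build an allelic count table from {gene: [(m, p, total), ...]}."""
    rows = []
    for gene, counts in per_sample_counts.items():
        n = len(counts)
        cr = crosses or ["BxC"] * (n // 2) + ["CxB"] * (n - n // 2)
        for i, (m, p, tot) in enumerate(counts):
            rows.append(
                {
                    "gene": gene,
                    "sample": f"s{i}",
                    "cross": cr[i],
                    "maternal_snp_reads": m,
                    "paternal_snp_reads": p,
                    "total_reads": tot,
                    "chrom": chrom,
                }
            )
    return pd.DataFrame(rows)


def make_meth_matrix(pos, levels, depth=50, chrom="chr1", groups=None):
    """Deterministic CpG matrix: meth = round(level * depth) per sample.

    ``levels`` maps group -> per-CpG level array; two replicates per
    blastocyst group, one per gamete group.
    """
    groups = groups or ["aha", "aha", "pha", "pha", "icsi", "icsi"]
    samples = []
    seen: dict[str, int] = {}
    for g in groups:
        seen[g] = seen.get(g, 0) + 1
        samples.append(f"{g}_{seen[g]}")
    pos = np.asarray(pos)
    n = len(pos)
    meth = np.zeros((n, len(groups)), dtype=int)
    total = np.full((n, len(groups)), depth, dtype=int)
    for j, g in enumerate(groups):
        lv = np.asarray(levels[g], dtype=float)
        meth[:, j] = np.round(lv * depth).astype(int)
    return CpGMethylationMatrix(
        chrom=np.full(n, chrom, dtype=object),
        pos=pos,
        meth=meth,
        total=total,
        samples=samples,
        groups=list(groups),
    )
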