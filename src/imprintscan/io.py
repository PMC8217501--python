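"""Readers and writers for the pipeline's on-disk formats.

Tabular data travel as TSV; methylation as Bismark-coverage-style files
(chrom, start, end, meth_percent, count_methylated, count_unmethylated);
peaks and TADs as BED6 (TAD score in column 5). Coordinates on disk follow
the BED dialect (0-based, half-open), matching the in-memory convention.
"""

from __future__ import annotations

import os
import numpy as np
import pandas as pd

ALLELIC_COLUMNS = [
    "gene", "sample", "cross", "maternal_snp_reads",
    "paternal_snp_reads", "total_reads", "chrom",
]


def write_allelic_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_allelic_counts(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELIC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allelic count table missing columns: {missing}")
    if (table["maternal_snp_reads"] < 0).any() or (table["paternal_snp_reads"] < 0).any():
        raise ValueError("negative allele counts")
    if table["cross"].isna().any():
        raise ValueError("every sample needs a cross direction")
    return table


def write_bismark_coverage(path, chrom, pos, meth, total) -> None:
    """One sample's CpG counts in Bismark coverage format."""
    unmeth = np.asarray(total) - np.asarray(meth)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * np.asarray(meth) / np.asarray(total), 0.0)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": pos,
            "end": np.asarray(pos) + 1,
            "meth_percent": np.round(pct, 4),
            "count_methylated": meth,
            "count_unmethylated": unmeth,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bismark_coverage(path) -> pd.DataFrame:
    """Parse one coverage file; methylation percent is recomputed from counts."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "meth_percent", "count_methylated", "count_unmethylated"],
        dtype={"chrom": str},
    )
    if df[["count_methylated", "count_unmethylated"]].lt(0).any().any():
        raise ValueError(f"negative counts in {path}")
    df["total"] = df["count_methylated"] + df["count_unmethylated"]
    return df[["chrom", "start", "count_methylated", "total"]]


def write_bed(df: pd.DataFrame, path, score_col: str | None = None, name_col: str | None = None,
              strand_col: str | None = None) -> None:
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": df[name_col] if name_col else ".",
            "score": df[score_col] if score_col else 0,
            "strand": df[strand_col] if strand_col else ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"malformed intervals in {path}")
    return df


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene", "chrom", "strand", "tss", "start", "end"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return ann


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; optional extra columns ignored; duplicates collapsed."""
    genes: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            g = line.split("\t")[0].split()[0]
            if g in seen:
                continue
            seen.add(g)
            genes.append(g)
    return genes
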