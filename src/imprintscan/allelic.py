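"""Parent-of-origin expression classification from reciprocal-cross counts.

Gene tiers
----------
BsX (blastocyst-skewed expressed): statistically significant allelic bias
(BH-adjusted p <= 0.1 against H0: log2FC = 0), |log2(maternal/paternal)| >
0.5, the same parental direction in forward and reverse crosses, and at
least 20 SNP-spanning reads in each cross.

BiX (blastocyst-imprinted expressed): BsX genes whose per-sample allelic
ratio reaches 70:30 toward the called parent in at least 60% of samples of
each cross.

A separate TOST declares significant *biallelic* expression (H0:
|log2FC| >= 1, BH-adjusted p <= 0.1). Novelty labels compare calls with
published imprint catalogues (nBiX / nBsX / pubBsX / published_unconfirmed).

The bias statistic is a beta-binomial score test of maternal fraction = 0.5
with gene-wise overdispersion shrunk toward the across-gene median; allelic
counts condition on per-gene totals, so no size-factor normalisation enters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as st

__all__ = [
    "AllelicMatrices",
    "assign_allelic_reads",
    "filter_robust_expression",
    "test_allelic_bias",
    "test_equivalence",
    "classify_bsx_bix",
    "annotate_vs_published",
    "analyze_allelic",
]


# ---------------------------------------------------------------------------
# read-level SNP assignment (simplified stand-in for the Allelome.Pro step)


def assign_allelic_reads(
    read_records: Iterable[Mapping],
    snp_table: Mapping[tuple[str, int], tuple[str, str]],
    cross_direction: str,
) -> pd.DataFrame:
    """Count maternal/paternal reads per gene from SNP-base observations.

    Each read record carries ``gene``, ``positions`` (chrom, pos pairs) and
    ``bases``. A read votes by majority of its informative SNP bases for
    strain1 (B6) or strain2 (cast); ties and reads without informative SNPs
    are discarded, as are reads flagged ambiguous across transcripts
    (``ambiguous=True``). The sample's cross direction maps strain to parent:
    forward ("BxC") means B6 is the mother.
    """
    if cross_direction not in ("BxC", "CxB"):
        raise ValueError("cross_direction must be 'BxC' or 'CxB'")
    counts: dict[str, list[int]] = {}
    for rec in read_records:
        if rec.get("ambiguous"):
            continue
        votes = [0, 0]  # strain1, strain2
        for (chrom, pos), base in zip(rec["positions"], rec["bases"]):
            alleles = snp_table.get((chrom, pos))
            if alleles is None:
                continue
            a1, a2 = alleles
            if a1 == a2:
                raise ValueError(f"SNP at {chrom}:{pos} has identical alleles in both strains")
            if base == a1:
                votes[0] += 1
            elif base == a2:
                votes[1] += 1
        if votes[0] == votes[1]:
            continue  # uninformative or tied -> discard
        strain1_wins = votes[0] > votes[1]
        maternal = strain1_wins if cross_direction == "BxC" else not strain1_wins
        c = counts.setdefault(rec["gene"], [0, 0])
        c[0 if maternal else 1] += 1
    rows = [
        {"gene": g, "maternal_snp_reads": c[0], "paternal_snp_reads": c[1]}
        for g, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "maternal_snp_reads", "paternal_snp_reads"])


# ---------------------------------------------------------------------------
# table -> matrices


@dataclass
class AllelicMatrices:
    """Wide view of an allelic count table: one row per gene."""

    genes: np.ndarray
    chrom: np.ndarray
    samples: np.ndarray
    cross: np.ndarray            # per sample
    maternal: np.ndarray         # (genes, samples)
    paternal: np.ndarray
    total_reads: np.ndarray

    @property
    def snp_total(self) -> np.ndarray:
        return self.maternal + self.paternal

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "AllelicMatrices":
        piv = lambda col: table.pivot_table(
            index="gene", columns="sample", values=col, aggfunc="sum", fill_value=0
        )
        m = piv("maternal_snp_reads")
        p = piv("paternal_snp_reads").reindex(index=m.index, columns=m.columns, fill_value=0)
        tot = piv("total_reads").reindex(index=m.index, columns=m.columns, fill_value=0)
        sample_cross = table.drop_duplicates("sample").set_index("sample")["cross"]
        gene_chrom = table.drop_duplicates("gene").set_index("gene")["chrom"]
        return cls(
            genes=m.index.to_numpy(),
            chrom=gene_chrom.reindex(m.index).to_numpy(),
            samples=m.columns.to_numpy(),
            cross=sample_cross.reindex(m.columns).to_numpy(),
            maternal=m.to_numpy(float),
            paternal=p.to_numpy(float),
            total_reads=tot.to_numpy(float),
        )


# ---------------------------------------------------------------------------
# filters and tests


def filter_robust_expression(
    table: pd.DataFrame,
    min_reads: int = 12,
    min_samples: int = 4,
    min_snp_reads: int = 10,
    exclude_chroms: Sequence[str] = ("chrX",),
) -> list[str]:
    """Genes with robust expression, testable allelic signal, not X-linked.

    A gene passes when its disjoint-exon total reaches ``min_reads`` in at
    least ``min_samples`` samples and at least one sample carries
    ``min_snp_reads`` SNP-spanning reads. X-linked genes are removed
    unconditionally (embryos are not sex-matched).
    """
    mats = AllelicMatrices.from_table(table)
    if mats.maternal.shape[1] < min_samples:
        raise ValueError(
            f"need at least {min_samples} usable samples, got {mats.maternal.shape[1]}"
        )
    robust = (mats.total_reads >= min_reads).sum(axis=1) >= min_samples
    has_snp = (mats.snp_total >= min_snp_reads).any(axis=1)
    autosomal = ~np.isin(mats.chrom, list(exclude_chroms))
    return list(mats.genes[robust & has_snp & autosomal])


def test_allelic_bias(
    table: pd.DataFrame | AllelicMatrices,
    genes: Sequence[str] | None = None,
    shrink: float = 0.3,
) -> pd.DataFrame:
    """Per-gene allelic bias test (H0: log2FC = 0) with BH adjustment.

    Returns a frame with log2fc, z, p_bias, padj_bias, per-cross SNP reads
    and the per-sample maternal fractions used downstream. Genes with zero
    SNP reads everywhere are flagged untestable (NaN p, excluded from BH).
    """
    mats = table if isinstance(table, AllelicMatrices) else AllelicMatrices.from_table(table)
    if genes is not None:
        keep = np.isin(mats.genes, list(genes))
        mats = AllelicMatrices(
            mats.genes[keep], mats.chrom[keep], mats.samples, mats.cross,
            mats.maternal[keep], mats.paternal[keep], mats.total_reads[keep],
        )
    m, t = mats.maternal, mats.snp_total
    rho = st.estimate_overdispersion(m, t, shrink=shrink)
    z, p = st.betabinom_score_test(m, t, rho)
    lfc = st.pooled_log2fc(m.sum(axis=1), mats.paternal.sum(axis=1))
    fwd = mats.cross == "BxC"
    res = pd.DataFrame(
        {
            "gene": mats.genes,
            "chrom": mats.chrom,
            "log2fc": lfc,
            "z": z,
            "p_bias": p,
            "padj_bias": st.bh_adjust(p),
            "rho": rho,
            "snp_reads_forward": t[:, fwd].sum(axis=1).astype(int),
            "snp_reads_reverse": t[:, ~fwd].sum(axis=1).astype(int),
        }
    )
    res.attrs["matrices"] = mats
    return res


def test_equivalence(
    table: pd.DataFrame | AllelicMatrices,
    genes: Sequence[str] | None = None,
    margin_log2: float = 1.0,
    shrink: float = 0.3,
) -> pd.DataFrame:
    """TOST for biallelic expression (H0: |log2FC| >= margin), BH-adjusted."""
    mats = table if isinstance(table, AllelicMatrices) else AllelicMatrices.from_table(table)
    if genes is not None:
        keep = np.isin(mats.genes, list(genes))
        mats = AllelicMatrices(
            mats.genes[keep], mats.chrom[keep], mats.samples, mats.cross,
            mats.maternal[keep], mats.paternal[keep], mats.total_reads[keep],
        )
    m, t = mats.maternal, mats.snp_total
    rho = st.estimate_overdispersion(m, t, shrink=shrink)
    lfc, se = st.log2fc_and_se(m, t, rho)
    p = st.tost_equivalence(lfc, se, margin=margin_log2)
    return pd.DataFrame(
        {
            "gene": mats.genes,
            "log2fc_tost": lfc,
            "se_log2fc": se,
            "p_equiv": p,
            "padj_equiv": st.bh_adjust(p),
        }
    )


def classify_bsx_bix(
    results: pd.DataFrame,
    table: pd.DataFrame | AllelicMatrices,
    padj_max: float = 0.1,
    min_log2fc: float = 0.5,
    ratio: float = 0.7,
    ratio_frac: float = 0.6,
    min_cross_reads: int = 20,
    min_sample_snp_reads: int = 5,
) -> pd.DataFrame:
    """Apply the BsX / BiX rule cascade to bias-test results.

    ``results`` must come from :func:`test_allelic_bias` (BH already applied
    over the tested family). Samples with fewer than
    ``min_sample_snp_reads`` SNP reads for a gene do not enter the 70:30
    rule's denominator.
    """
    mats = table if isinstance(table, AllelicMatrices) else AllelicMatrices.from_table(table)
    order = {g: i for i, g in enumerate(mats.genes)}
    idx = np.array([order[g] for g in results["gene"]])
    m = mats.maternal[idx]
    p = mats.paternal[idx]
    t = m + p
    fwd = mats.cross == "BxC"

    m_f, p_f = m[:, fwd].sum(axis=1), p[:, fwd].sum(axis=1)
    m_r, p_r = m[:, ~fwd].sum(axis=1), p[:, ~fwd].sum(axis=1)
    dir_f = np.sign(m_f - p_f)
    dir_r = np.sign(m_r - p_r)
    consistent = (dir_f == dir_r) & (dir_f != 0)
    enough_reads = ((m_f + p_f) >= min_cross_reads) & ((m_r + p_r) >= min_cross_reads)

    lfc = results["log2fc"].to_numpy()
    padj = results["padj_bias"].to_numpy()
    bsx = (
        ~np.isnan(padj)
        & (padj <= padj_max)
        & (np.abs(lfc) > min_log2fc)
        & consistent
        & enough_reads
    )
    parent = np.where(lfc > 0, "maternal", "paternal")

    with np.errstate(invalid="ignore", divide="ignore"):
        frac_m = np.where(t > 0, m / np.maximum(t, 1), np.nan)
    toward = np.where(parent[:, None] == "maternal", frac_m, 1.0 - frac_m)
    usable = t >= min_sample_snp_reads
    hit = (toward >= ratio) & usable

    def _cross_frac(sel: np.ndarray) -> np.ndarray:
        n_use = usable[:, sel].sum(axis=1)
        n_hit = hit[:, sel].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_use > 0, n_hit / np.maximum(n_use, 1), 0.0)

    frac_hit_f = _cross_frac(fwd)
    frac_hit_r = _cross_frac(~fwd)
    bix = bsx & (frac_hit_f >= ratio_frac) & (frac_hit_r >= ratio_frac)

    out = results.copy()
    out["consistent_flag"] = consistent
    out["bsx"] = bsx
    out["bix"] = bix
    out["parent"] = np.where(bsx, parent, "NA")
    out["frac_samples_ratio_forward"] = frac_hit_f
    out["frac_samples_ratio_reverse"] = frac_hit_r
    out["category"] = np.select(
        [bix, bsx], ["BiX", "BsX_only"], default="neither"
    )
    return out


def annotate_vs_published(
    calls: pd.DataFrame,
    published_genes: Sequence[str],
    hcon_genes: Sequence[str] = (),
    noncanonical_genes: Sequence[str] = (),
    equiv_padj_max: float = 0.1,
) -> pd.DataFrame:
    """Novelty labels against published imprint catalogues.

    BsX genes found in the published list become pubBsX; BsX genes not
    published become nBsX (and nBiX if BiX); published genes without a BsX
    call become published_unconfirmed. If the calls carry equivalence
    results (``padj_equiv``), genes with adjusted p <= 0.1 and no BsX call
    are labelled ``equivalent``.
    """
    published = set(published_genes)
    out = calls.copy()
    bsx = out["bsx"].to_numpy(bool)
    in_pub = out["gene"].isin(published).to_numpy()
    novelty = np.full(len(out), "other", dtype=object)
    novelty[bsx & in_pub] = "pubBsX"
    novelty[bsx & ~in_pub] = "nBsX"
    if "bix" in out:
        novelty[out["bix"].to_numpy(bool) & ~in_pub] = "nBiX"
    novelty[~bsx & in_pub] = "published_unconfirmed"
    out["novelty"] = novelty
    out["hcon"] = out["gene"].isin(set(hcon_genes))
    out["noncanonical"] = out["gene"].isin(set(noncanonical_genes))
    if "padj_equiv" in out.columns:
        equiv = (~out["padj_equiv"].isna()) & (out["padj_equiv"] <= equiv_padj_max) & ~bsx
        out.loc[equiv & (out["category"] == "neither"), "category"] = "equivalent"
        out["equivalent"] = equiv
    return out


def analyze_allelic(
    table: pd.DataFrame,
    published_genes: Sequence[str] = (),
    hcon_genes: Sequence[str] = (),
    noncanonical_genes: Sequence[str] = (),
    **params,
) -> pd.DataFrame:
    """Full stage: robust-expression filter, bias + equivalence tests, calls."""
    filter_kw = {
        k: params.pop(k)
        for k in ("min_reads", "min_samples", "min_snp_reads", "exclude_chroms")
        if k in params
    }
    classify_kw = {
        k: params.pop(k)
        for k in ("padj_max", "min_log2fc", "ratio", "ratio_frac",
                  "min_cross_reads", "min_sample_snp_reads")
        if k in params
    }
    shrink = params.pop("shrink", 0.3)
    margin = params.pop("margin_log2", 1.0)
    if params:
        raise TypeError(f"unknown parameters: {sorted(params)}")
    genes = filter_robust_expression(table, **filter_kw)
    mats = AllelicMatrices.from_table(table)
    bias = test_allelic_bias(mats, genes=genes, shrink=shrink)
    equiv = test_equivalence(mats, genes=genes, margin_log2=margin, shrink=shrink)
    res = bias.merge(equiv, on="gene")
    calls = classify_bsx_bix(res, mats, **classify_kw)
    return annotate_vs_published(
        calls, published_genes, hcon_genes, noncanonical_genes,
        equiv_padj_max=classify_kw.get("padj_max", 0.1),
    )
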