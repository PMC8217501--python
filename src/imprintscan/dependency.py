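"""Functional dependence of imprinted expression on maternal regulators.

From matched WT / maternal-KO allelic count tables (one pair per regulator,
mDnmt3l or mEed), a gene is called *dependent* when (1) it shows significant
parent-of-origin bias in WT (BH-adjusted p <= 0.1 within the tested family),
(2) its allelic ratio depends significantly on genotype (two-sample
beta-binomial likelihood-ratio test, BH-adjusted p <= 0.05), and (3) the
allelic bias is reduced in the KO. mEed dependence is only considered for
genes expressed with paternal bias in WT, since maternal H3K27me3 represses
the maternal allele. Each KO is compared only against its own matched WT.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as st
from .allelic import AllelicMatrices

__all__ = [
    "check_no_global_de",
    "test_wt_bias",
    "test_genotype_dependence",
    "classify_dependence",
    "compare_amplitudes",
    "analyze_dependency",
]


def check_no_global_de(
    wt_table: pd.DataFrame, ko_table: pd.DataFrame, padj_max: float = 0.1
) -> list[str]:
    """Genes differentially expressed between WT and KO on allele-summed totals.

    Welch t-test on log2 normalised total (disjoint-exon) counts with
    median-of-ratios size factors (robust to a few strongly shifted genes),
    BH-adjusted. A compliant KO dataset returns an empty list; a warning is
    emitted otherwise.
    """
    import warnings

    wt = AllelicMatrices.from_table(wt_table)
    ko = AllelicMatrices.from_table(ko_table)
    if wt.total_reads.shape[1] < 2 or ko.total_reads.shape[1] < 2:
        raise ValueError("need >= 2 samples per genotype")
    common = np.intersect1d(wt.genes, ko.genes)
    wi = {g: i for i, g in enumerate(wt.genes)}
    ki = {g: i for i, g in enumerate(ko.genes)}
    a = wt.total_reads[[wi[g] for g in common]]
    b = ko.total_reads[[ki[g] for g in common]]

    counts = np.hstack([a, b])
    with np.errstate(divide="ignore"):
        loggm = np.log(counts + 0.5).mean(axis=1, keepdims=True)
        ratios = np.log(counts + 0.5) - loggm
    size = np.exp(np.median(ratios, axis=0))

    def lognorm(x, s):
        return np.log2((x + 0.5) / s)

    n_wt = a.shape[1]
    t, p = sps.ttest_ind(
        lognorm(a, size[:n_wt]), lognorm(b, size[n_wt:]), axis=1, equal_var=False
    )
    padj = st.bh_adjust(p)
    hits = [g for g, q in zip(common, padj) if np.isfinite(q) and q <= padj_max]
    if hits:
        warnings.warn(
            f"{len(hits)} genes differentially expressed between WT and KO; "
            "allelic dependence calls may be confounded"
        )
    return hits


def test_wt_bias(
    wt_table: pd.DataFrame, genes: Sequence[str] | None = None, shrink: float = 0.3
) -> pd.DataFrame:
    """Parent-of-origin bias in WT samples, BH within the restricted family.

    ``genes`` is the BsX-union-published universe; BH is applied over that
    family only.
    """
    mats = AllelicMatrices.from_table(wt_table)
    if genes is not None:
        keep = np.isin(mats.genes, list(genes))
    else:
        keep = np.ones(len(mats.genes), bool)
    m = mats.maternal[keep]
    t = mats.maternal[keep] + mats.paternal[keep]
    rho = st.estimate_overdispersion(m, t, shrink=shrink)
    z, p = st.betabinom_score_test(m, t, rho)
    lfc = st.pooled_log2fc(m.sum(axis=1), (t - m).sum(axis=1))
    return pd.DataFrame(
        {
            "gene": mats.genes[keep],
            "wt_log2fc": lfc,
            "wt_p": p,
            "wt_padj": st.bh_adjust(p),
            "rho": rho,
            "expressed_parent_in_wt": np.where(lfc > 0, "maternal", "paternal"),
        }
    )


def test_genotype_dependence(
    wt_table: pd.DataFrame,
    ko_table: pd.DataFrame,
    wt_bias: pd.DataFrame,
    wt_padj_max: float = 0.1,
) -> pd.DataFrame:
    """Allelic-ratio dependence on genotype for WT-biased genes.

    Two-sample beta-binomial LRT of equal maternal fraction in WT vs KO for
    every gene with wt_padj <= wt_padj_max; BH over that family.
    ``reduced_in_ko`` compares pooled |log2fc| between genotypes. Genes with
    zero KO coverage are flagged untestable.
    """
    wt = AllelicMatrices.from_table(wt_table)
    ko = AllelicMatrices.from_table(ko_table)
    wi = {g: i for i, g in enumerate(wt.genes)}
    ki = {g: i for i, g in enumerate(ko.genes)}
    tested = wt_bias[
        (~wt_bias["wt_padj"].isna()) & (wt_bias["wt_padj"] <= wt_padj_max)
    ].reset_index(drop=True)
    rows = []
    for row in tested.itertuples():
        g = row.gene
        if g not in ki:
            rows.append({"gene": g, "ko_log2fc": np.nan, "interaction_p": np.nan,
                         "reduced_in_ko": False, "untestable": True})
            continue
        m1 = wt.maternal[wi[g]]
        t1 = m1 + wt.paternal[wi[g]]
        m2 = ko.maternal[ki[g]]
        t2 = m2 + ko.paternal[ki[g]]
        if t2.sum() == 0:
            rows.append({"gene": g, "ko_log2fc": np.nan, "interaction_p": np.nan,
                         "reduced_in_ko": False, "untestable": True})
            continue
        _, p = st.two_sample_bb_lrt(m1, t1, m2, t2, rho=float(row.rho))
        ko_lfc = float(st.pooled_log2fc(m2.sum(), (t2 - m2).sum()))
        rows.append(
            {
                "gene": g,
                "ko_log2fc": ko_lfc,
                "interaction_p": p,
                "reduced_in_ko": bool(abs(ko_lfc) < abs(row.wt_log2fc)),
                "untestable": False,
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene", "ko_log2fc", "interaction_p", "reduced_in_ko", "untestable"]
    )
    out["interaction_padj"] = st.bh_adjust(out["interaction_p"].to_numpy(float)) if len(out) else []
    return tested.merge(out, on="gene", how="left")


def _dependent_flags(results: pd.DataFrame, interaction_padj_max: float = 0.05) -> pd.Series:
    return (
        (~results["interaction_padj"].isna())
        & (results["interaction_padj"] <= interaction_padj_max)
        & results["reduced_in_ko"].astype("boolean").fillna(False).astype(bool)
    )


def classify_dependence(
    results_dnmt3l: pd.DataFrame,
    results_eed: pd.DataFrame,
    interaction_padj_max: float = 0.05,
) -> pd.DataFrame:
    """Combine per-regulator dependence into mDnmt3l / mEed / both / neither.

    Maternally expressed genes can never be mEed-dependent (maternal
    H3K27me3 silences the maternal allele, so Eed loss can only de-repress
    paternally expressed imprints). Genes failing the WT-bias gate in both
    datasets are 'untested'.
    """
    dep_d = results_dnmt3l.assign(dep=_dependent_flags(results_dnmt3l, interaction_padj_max))
    dep_e = results_eed.assign(dep=_dependent_flags(results_eed, interaction_padj_max))
    eed_ok = dep_e["expressed_parent_in_wt"] == "paternal"
    dep_e["dep"] &= eed_ok
    merged = dep_d[["gene", "wt_log2fc", "wt_padj", "expressed_parent_in_wt", "dep"]].merge(
        dep_e[["gene", "dep", "expressed_parent_in_wt"]],
        on="gene", how="outer", suffixes=("_dnmt3l", "_eed"),
    )
    d = merged["dep_dnmt3l"].astype("boolean").fillna(False).astype(bool)
    e = merged["dep_eed"].astype("boolean").fillna(False).astype(bool)
    merged["dependence"] = np.select(
        [d & e, d, e], ["both", "mDnmt3l", "mEed"], default="neither"
    )
    merged["expressed_parent_in_wt"] = merged["expressed_parent_in_wt_dnmt3l"].fillna(
        merged["expressed_parent_in_wt_eed"]
    )
    return merged[["gene", "wt_log2fc", "wt_padj", "expressed_parent_in_wt",
                   "dep_dnmt3l", "dep_eed", "dependence"]]


def compare_amplitudes(
    wt_lfc: Sequence[float],
    ko_lfc: Sequence[float],
    other_wt_lfc: Sequence[float] | None = None,
) -> dict:
    """Allelic-bias amplitude comparisons on |log2FC|.

    Paired two-tailed Wilcoxon signed-rank WT vs KO within a dataset (exact
    null when n <= 25, normal approximation with continuity correction
    otherwise); optional two-tailed rank-sum between the two WT datasets.
    """
    import warnings

    a = np.abs(np.asarray(wt_lfc, float))
    b = np.abs(np.asarray(ko_lfc, float))
    n = len(a)
    if n < 5:
        warnings.warn(f"only {n} genes; signed-rank p-value is coarse")
    mode = "exact" if n <= 25 else "approx"
    if np.allclose(a, b):
        signed_p = 1.0
    else:
        signed_p = float(
            sps.wilcoxon(a, b, zero_method="wilcox", correction=(mode == "approx"),
                         mode=mode).pvalue
        )
    out = {"signed_rank_p": signed_p, "n": n, "median_wt": float(np.median(a)),
           "median_ko": float(np.median(b))}
    if other_wt_lfc is not None:
        c = np.abs(np.asarray(other_wt_lfc, float))
        method = "exact" if max(len(a), len(c)) <= 25 else "asymptotic"
        out["rank_sum_p"] = float(
            sps.mannwhitneyu(a, c, alternative="two-sided", method=method).pvalue
        )
    return out


def analyze_dependency(
    wt_dnmt3l: pd.DataFrame,
    ko_dnmt3l: pd.DataFrame,
    wt_eed: pd.DataFrame,
    ko_eed: pd.DataFrame,
    gene_universe: Sequence[str],
    wt_padj_max: float = 0.1,
    interaction_padj_max: float = 0.05,
) -> pd.DataFrame:
    """Full stage on both regulator datasets, each against its own WT."""
    check_no_global_de(wt_dnmt3l, ko_dnmt3l)
    check_no_global_de(wt_eed, ko_eed)
    res_d = test_genotype_dependence(
        wt_dnmt3l, ko_dnmt3l, test_wt_bias(wt_dnmt3l, genes=gene_universe),
        wt_padj_max=wt_padj_max,
    )
    res_e = test_genotype_dependence(
        wt_eed, ko_eed, test_wt_bias(wt_eed, genes=gene_universe),
        wt_padj_max=wt_padj_max,
    )
    out = classify_dependence(res_d, res_e, interaction_padj_max=interaction_padj_max)
    _assert_dependence_contract(out)
    return out


def _assert_dependence_contract(out: pd.DataFrame) -> None:
    """mEed dependence implies paternal WT expression; asserted on every output."""
    eed = out["dependence"].isin(["mEed", "both"])
    assert (out.loc[eed, "expressed_parent_in_wt"] == "paternal").all()
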