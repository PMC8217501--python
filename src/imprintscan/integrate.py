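"""Integration of imprint calls with DMRs, H3K27me3, TADs and clusters.

Distances between genes and DMRs are measured TSS-to-DMR-centre (the same
convention that defines TAD co-membership); H3K27me3 is linked through a
TSS +/- 5 kb window against allele- and gamete-specific peak sets; DMR-gene
TAD co-occurrence is tested against a distance-preserving circular-shift
null; imprinted gene clusters are single-linkage chains of eligible TSSs
within 250 kb.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "associate_dmr_gene",
    "associate_h3k27me3",
    "tad_cooccurrence_test",
    "find_clusters",
    "feature_distribution",
    "filter_tads",
    "integrate_all",
]


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in intervals.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def _overlaps(trees: Mapping[str, IntervalTree], chrom, start, end) -> bool:
    t = trees.get(chrom)
    return bool(t and t.overlap(start, end))


def filter_tads(tads: pd.DataFrame, min_score: float = 0.5) -> pd.DataFrame:
    """Keep TADs with score >= min_score (the published filtering rule)."""
    if "score" not in tads.columns:
        return tads.reset_index(drop=True)
    return tads[tads["score"] >= min_score].reset_index(drop=True)


def associate_dmr_gene(
    annotation: pd.DataFrame,
    dmrs: pd.DataFrame,
    windows: tuple[int, int] = (100_000, 250_000),
    tss_window: int = 10_000,
) -> pd.DataFrame:
    """Nearest-DMR distances and window membership per gene.

    Distance is |TSS - DMR centre| on the same chromosome. Genes on
    chromosomes without any DMR get NaN distance and all-false booleans.
    """
    centres = ((dmrs["start"] + dmrs["end"]) // 2).to_numpy() if len(dmrs) else np.array([], int)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if len(dmrs):
        for chrom, sub in dmrs.assign(centre=centres).groupby("chrom"):
            order = np.argsort(sub["centre"].to_numpy())
            by_chrom[chrom] = (
                sub["centre"].to_numpy()[order],
                sub["dmr_id"].to_numpy()[order] if "dmr_id" in sub else sub.index.to_numpy()[order],
            )
    rows = []
    w1, w2 = sorted(windows)
    for g in annotation.itertuples():
        entry = by_chrom.get(g.chrom)
        if entry is None:
            rows.append(
                {
                    "gene": g.gene,
                    "nearest_dmr": None,
                    "dmr_distance": np.nan,
                    f"within_{w1 // 1000}kb": False,
                    f"within_{w2 // 1000}kb": False,
                    "within_10kb_of_tss": False,
                }
            )
            continue
        cent, ids = entry
        j = np.searchsorted(cent, g.tss)
        best, best_d = None, np.inf
        for k in (j - 1, j):
            if 0 <= k < len(cent):
                d = abs(int(g.tss) - int(cent[k]))
                if d < best_d:
                    best, best_d = ids[k], d
        rows.append(
            {
                "gene": g.gene,
                "nearest_dmr": best,
                "dmr_distance": float(best_d),
                f"within_{w1 // 1000}kb": best_d <= w1,
                f"within_{w2 // 1000}kb": best_d <= w2,
                "within_10kb_of_tss": best_d <= tss_window,
            }
        )
    return pd.DataFrame(rows)


def associate_h3k27me3(
    annotation: pd.DataFrame,
    peaks: Mapping[str, pd.DataFrame],
    tss_half_width: int = 5000,
) -> pd.DataFrame:
    """Allele- and gamete-specific H3K27me3 status at each gene's TSS.

    TSS status: maternal / paternal if the corresponding allelic ICM peak
    set overlaps TSS +/- tss_half_width (both allelic sets -> both);
    'both' also when only the allele-agnostic ICM set overlaps; none
    otherwise. Gamete status from oocyte/sperm peak-set exclusivity.
    Missing peak sets are tolerated (treated as empty).
    """
    import warnings

    sets = {}
    for name in ("ICM_maternal", "ICM_paternal", "ICM_all", "oocyte", "sperm"):
        if name in peaks and peaks[name] is not None:
            sets[name] = _trees(peaks[name])
        else:
            warnings.warn(f"peak set {name!r} missing; treated as empty")
            sets[name] = {}
    rows = []
    for g in annotation.itertuples():
        lo = max(0, int(g.tss) - tss_half_width)
        hi = int(g.tss) + tss_half_width
        mat = _overlaps(sets["ICM_maternal"], g.chrom, lo, hi)
        pat = _overlaps(sets["ICM_paternal"], g.chrom, lo, hi)
        allp = _overlaps(sets["ICM_all"], g.chrom, lo, hi)
        if mat and pat:
            tss_status = "both"
        elif mat:
            tss_status = "maternal"
        elif pat:
            tss_status = "paternal"
        elif allp:
            tss_status = "both"
        else:
            tss_status = "none"
        oo = _overlaps(sets["oocyte"], g.chrom, lo, hi)
        sp = _overlaps(sets["sperm"], g.chrom, lo, hi)
        gamete = (
            "both_gametes" if (oo and sp)
            else "oocyte_specific" if oo
            else "sperm_specific" if sp
            else "neither"
        )
        rows.append({"gene": g.gene, "k27_tss_status": tss_status, "k27_gamete_status": gamete})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TAD co-occurrence with a distance-preserving circular-shift null


def _tad_membership(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """TAD index per position, -1 outside every (score-filtered) TAD."""
    j = np.searchsorted(starts, pos, side="right") - 1
    j = j.clip(min=0)
    inside = (pos >= starts[j]) & (pos < ends[j])
    return np.where(inside, j, -1)


def _cooccurrence_count(
    gene_tad: np.ndarray, gene_chrom_code: np.ndarray,
    dmr_tad: np.ndarray, dmr_chrom_code: np.ndarray, n_tads_per_chrom: Sequence[int],
) -> int:
    """Genes whose TSS shares a TAD with >= 1 DMR centre."""
    count = 0
    for c, _ in enumerate(n_tads_per_chrom):
        g = gene_tad[gene_chrom_code == c]
        d = dmr_tad[dmr_chrom_code == c]
        occupied = np.unique(d[d >= 0])
        count += int(np.isin(g[g >= 0], occupied).sum())
    return count


def tad_cooccurrence_test(
    annotation: pd.DataFrame,
    dmrs: pd.DataFrame,
    tads: pd.DataFrame,
    genes: Sequence[str] | None = None,
    n_shifts: int = 2000,
    seed: int = 0,
    min_score: float = 0.5,
) -> dict:
    """Empirical test of gene-DMR co-occurrence within TADs.

    Observed: number of (selected) genes with at least one DMR centre in the
    same score-filtered TAD as their TSS. Null: per iteration one uniform
    circular offset per chromosome applied jointly to all TSSs and DMR
    centres (wrap-around at chromosome length), preserving every pairwise
    gene-DMR distance. p = (1 + #{null >= observed}) / (1 + n_shifts).
    Genes on chromosomes absent from the TAD set are excluded.
    """
    tads = filter_tads(tads, min_score)
    ann = annotation if genes is None else annotation[annotation["gene"].isin(set(genes))]
    chroms = sorted(set(tads["chrom"]))
    code = {c: i for i, c in enumerate(chroms)}
    ann = ann[ann["chrom"].isin(code)].reset_index(drop=True)
    dm = dmrs[dmrs["chrom"].isin(code)].reset_index(drop=True)
    rng = np.random.default_rng(seed)

    chrom_len = {}
    tad_by_chrom = {}
    for c in chroms:
        sub = tads[tads["chrom"] == c].sort_values("start")
        tad_by_chrom[c] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        chrom_len[c] = int(sub["end"].max())

    g_pos = ann["tss"].to_numpy(int)
    g_code = ann["chrom"].map(code).to_numpy(int)
    d_pos = ((dm["start"] + dm["end"]) // 2).to_numpy(int) if len(dm) else np.array([], int)
    d_code = dm["chrom"].map(code).to_numpy(int) if len(dm) else np.array([], int)

    def counts_for_offsets(offsets: np.ndarray) -> np.ndarray:
        """Co-occurrence count per shift; one joint offset per chromosome.

        Vectorised: TAD membership for all shifted positions at once, then a
        per-shift occupancy table (shifts x TADs) scattered from the DMR
        memberships.
        """
        n_it = offsets.shape[0]
        total = np.zeros(n_it, dtype=int)
        for c in chroms:
            i = code[c]
            starts, ends = tad_by_chrom[c]
            L = chrom_len[c]
            off = offsets[:, i][:, None]
            g = g_pos[g_code == i]
            d = d_pos[d_code == i]
            if len(g) == 0 or len(d) == 0:
                continue
            gp = (g[None, :] + off) % L
            dp = (d[None, :] + off) % L
            gt = _tad_membership(gp.ravel(), starts, ends).reshape(n_it, -1)
            dt = _tad_membership(dp.ravel(), starts, ends).reshape(n_it, -1)
            occ = np.zeros((n_it, len(starts) + 1), dtype=bool)
            it_idx = np.repeat(np.arange(n_it), dt.shape[1])
            valid = dt.ravel() >= 0
            occ[it_idx[valid], dt.ravel()[valid]] = True
            g_valid = gt >= 0
            hit = occ[np.arange(n_it)[:, None], np.clip(gt, 0, None)] & g_valid
            total += hit.sum(axis=1)
        return total

    lengths = np.array([chrom_len[c] for c in chroms])
    observed = int(counts_for_offsets(np.zeros((1, len(chroms)), dtype=int))[0])
    offsets = rng.integers(0, lengths[None, :].repeat(n_shifts, axis=0))
    null_counts = counts_for_offsets(offsets)
    p = (1.0 + int((null_counts >= observed).sum())) / (1.0 + n_shifts)
    return {
        "observed": observed,
        "n_genes": len(ann),
        "empirical_p": p,
        "null_counts": null_counts,
    }


def find_clusters(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    max_gap: int = 250_000,
    eligible_novelty: Sequence[str] = ("nBiX", "nBsX", "pubBsX", "published_unconfirmed"),
) -> pd.DataFrame:
    """Single-linkage clusters of novel/published imprinted genes.

    Genes with an eligible novelty label are chained when consecutive TSSs
    on a chromosome are <= max_gap apart; chains of >= 2 genes are emitted.
    Cluster types mirror the published grouping: contains_pubBsX;
    published_only_no_blastocyst_bias (published members only, none BsX);
    published_plus_novel; novel_only.
    """
    elig = calls[calls["novelty"].isin(set(eligible_novelty))]
    merged = elig.merge(annotation[["gene", "chrom", "tss"]], on="gene", how="inner",
                        suffixes=("", "_ann"))
    if "chrom_ann" in merged:
        merged["chrom"] = merged["chrom"].fillna(merged["chrom_ann"])
    rows = []
    cid = 0
    for chrom, sub in merged.groupby("chrom"):
        sub = sub.sort_values("tss")
        tss = sub["tss"].to_numpy()
        breaks = np.flatnonzero(np.diff(tss) > max_gap)
        bounds = np.concatenate([[0], breaks + 1, [len(sub)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            members = sub.iloc[a:b]
            if len(members) < 2:
                continue
            nov = set(members["novelty"])
            has_novel = bool(nov & {"nBiX", "nBsX"})
            if "pubBsX" in nov:
                ctype = "contains_pubBsX"
            elif not has_novel:
                ctype = "published_only_no_blastocyst_bias"
            elif nov & {"published_unconfirmed"}:
                ctype = "published_plus_novel"
            else:
                ctype = "novel_only"
            cid += 1
            rows.append(
                {
                    "cluster_id": f"cluster{cid:02d}",
                    "chrom": chrom,
                    "start": int(members["tss"].min()),
                    "end": int(members["tss"].max()) + 1,
                    "n_genes": len(members),
                    "type": ctype,
                    "genes": ",".join(sorted(members["gene"]))
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster_id", "chrom", "start", "end", "n_genes", "type", "genes"]
    )


def feature_distribution(
    dmrs: pd.DataFrame,
    features: Mapping[str, pd.DataFrame],
    universe: pd.DataFrame,
    n_random: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of DMRs overlapping each feature class vs size-matched draws.

    For the DMR set and each of ``n_random`` equally sized samples drawn
    without replacement from the universe of tested candidate regions, the
    fraction of regions overlapping each feature (>= 1 bp) is computed; the
    background mean and sd are reported per feature.
    """
    if len(universe) < len(dmrs):
        raise ValueError("universe smaller than the DMR set; cannot sample without replacement")
    rng = np.random.default_rng(seed)
    trees = {name: _trees(df) for name, df in features.items()}

    def fractions(regions: pd.DataFrame) -> dict[str, float]:
        out = {}
        for name, tr in trees.items():
            hits = sum(
                _overlaps(tr, r.chrom, r.start, r.end) for r in regions.itertuples()
            )
            out[name] = hits / max(len(regions), 1)
        return out

    obs = fractions(dmrs)
    bg = {name: np.empty(n_random) for name in trees}
    uni = universe.reset_index(drop=True)
    for i in range(n_random):
        draw = uni.iloc[rng.choice(len(uni), size=len(dmrs), replace=False)]
        fr = fractions(draw)
        for name in trees:
            bg[name][i] = fr[name]
    return pd.DataFrame(
        {
            "feature": list(trees),
            "dmr_fraction": [obs[n] for n in trees],
            "background_mean": [bg[n].mean() for n in trees],
            "background_sd": [bg[n].std(ddof=1) for n in trees],
        }
    )


def integrate_all(
    calls: pd.DataFrame,
    dmrs: pd.DataFrame,
    annotation: pd.DataFrame,
    peaks: Mapping[str, pd.DataFrame],
    tads: pd.DataFrame,
    n_shifts: int = 2000,
    seed: int = 0,
    cluster_gap: int = 250_000,
) -> dict:
    """Association records, TAD test on BsX genes, and clusters in one call."""
    assoc = associate_dmr_gene(annotation, dmrs).merge(
        associate_h3k27me3(annotation, peaks), on="gene"
    )
    bsx_genes = calls.loc[calls["bsx"], "gene"] if "bsx" in calls else calls["gene"]
    tad = tad_cooccurrence_test(
        annotation, dmrs, tads, genes=list(bsx_genes), n_shifts=n_shifts, seed=seed
    )
    same_tad = _same_tad_flags(annotation, dmrs, tads)
    assoc = assoc.merge(same_tad, on="gene", how="left")
    clusters = find_clusters(calls, annotation, max_gap=cluster_gap)
    return {"associations": assoc, "tad_test": tad, "clusters": clusters}


def _same_tad_flags(annotation, dmrs, tads, min_score: float = 0.5) -> pd.DataFrame:
    tads = filter_tads(tads, min_score)
    flags = []
    for chrom, sub in annotation.groupby("chrom"):
        t = tads[tads["chrom"] == chrom].sort_values("start")
        if len(t) == 0:
            flags.extend({"gene": g, "same_tad_dmr": False} for g in sub["gene"])
            continue
        starts, ends = t["start"].to_numpy(), t["end"].to_numpy()
        d = dmrs[dmrs["chrom"] == chrom]
        centres = ((d["start"] + d["end"]) // 2).to_numpy(int) if len(d) else np.array([], int)
        d_tad = _tad_membership(centres, starts, ends) if len(centres) else np.array([], int)
        occupied = set(d_tad[d_tad >= 0].tolist())
        g_tad = _tad_membership(sub["tss"].to_numpy(int), starts, ends)
        flags.extend(
            {"gene": g, "same_tad_dmr": bool(tt >= 0 and tt in occupied)}
            for g, tt in zip(sub["gene"], g_tad)
        )
    return pd.DataFrame(flags)
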