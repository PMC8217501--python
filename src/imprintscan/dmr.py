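"""Parent-of-origin DMR calling from uniparental vs biparental methylomes.

Androgenetic (aha, paternal-only) and parthenogenetic (pha, maternal-only)
blastocyst methylomes are contrasted against biparental ICSI controls.
Candidate regions are maximal runs of neighbouring CpGs whose pooled
pha - aha difference keeps a constant sign and magnitude; regions are scored
with a coverage-weighted, arcsine-transformed group difference against a
pooled label-permutation null, then pushed through the printed filter
cascade (FDR <= 0.1, ICSI strictly intermediate, |aha - pha| >= 30
percentage points, |beta_aha| >= 0.25, |beta_pha| >= 0.25, >= 100 reads
total coverage, >= 100 bp).

beta_aha / beta_pha are allele-level effect sizes inferred from the
uniparental-vs-biparental contrast: a biparental methylome averages the two
parental alleles, so the effect on one parental allele is twice the
group-vs-ICSI difference (beta_group = 2 * (mean_group - mean_ICSI)). The
raw mixture-scale difference is available via ``beta_scale="mixture"``.

Each DMR's gametic origin is classified with explicit threshold rules on
oocyte and sperm methylation (classes C1-C5), so class recovery is testable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as iomod
from . import stats as st

__all__ = [
    "CpGMethylationMatrix",
    "read_methylation",
    "filter_cpgs",
    "detect_candidate_regions",
    "score_and_test_regions",
    "filter_dmrs",
    "classify_dmr_origin",
    "recover_known_regions",
    "call_dmrs",
    "DMR_FILTER_PARAMS",
]

UNIPARENTAL_GROUPS = ("aha", "pha")
ORIGIN_CLASSES = (
    "C1_gamete_unmethylated",
    "C2_oocyte_specific",
    "C3_oocyte_biased",
    "C4_preimplantation_established",
    "C5_sperm_methylated",
)

DMR_FILTER_PARAMS = dict(
    fdr=0.1, min_diff_pp=30.0, min_beta=0.25, min_len=100, min_cov=100
)


@dataclass
class CpGMethylationMatrix:
    """Per-CpG methylated/total counts for a set of samples.

    Positions are 0-based and strictly increasing within each chromosome;
    sample groups come from {aha, pha, icsi, oocyte, sperm, esc, somatic}.
    """

    chrom: np.ndarray
    pos: np.ndarray
    meth: np.ndarray   # (n_cpgs, n_samples)
    total: np.ndarray
    samples: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        if np.any(self.meth > self.total) or np.any(self.meth < 0):
            raise ValueError("need 0 <= count_methylated <= count_total")
        # enforce sort by (chrom, pos) and strict position increase per chrom
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.meth = self.meth[order]
            self.total = self.total[order]
        same = (self.chrom[1:] == self.chrom[:-1]) & (self.pos[1:] <= self.pos[:-1])
        if same.any():
            raise ValueError("duplicate CpG positions within a chromosome")

    @property
    def n_cpgs(self) -> int:
        return len(self.pos)

    def sample_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.groups) == group)

    def subset(self, mask: np.ndarray) -> "CpGMethylationMatrix":
        return CpGMethylationMatrix(
            self.chrom[mask], self.pos[mask], self.meth[mask], self.total[mask],
            list(self.samples), list(self.groups),
        )

    def pooled_level(self, group: str) -> np.ndarray:
        """Per-CpG methylation level pooling counts across a group's replicates."""
        idx = self.sample_indices(group)
        m = self.meth[:, idx].sum(axis=1)
        t = self.total[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, m / np.maximum(t, 1), np.nan)

    def write(self, outdir, prefix: str = "") -> list[str]:
        """One Bismark-coverage file per sample; returns the paths."""
        import os

        paths = []
        for j, name in enumerate(self.samples):
            path = os.path.join(outdir, f"{prefix}{name}.cov")
            iomod.write_bismark_coverage(
                path, self.chrom, self.pos, self.meth[:, j], self.total[:, j]
            )
            paths.append(path)
        return paths


def read_methylation(
    files: Sequence[tuple[str, str]], group_map: Mapping[str, str]
) -> CpGMethylationMatrix:
    """Build a matrix from (sample_id, path) coverage files.

    Files sharing a sample id are summed position-wise; distinct samples are
    kept as separate columns. Positions absent from a sample get zero counts.
    """
    per_sample: dict[str, pd.DataFrame] = {}
    for sample_id, path in files:
        df = iomod.read_bismark_coverage(path)
        if sample_id in per_sample:
            df = (
                pd.concat([per_sample[sample_id], df])
                .groupby(["chrom", "start"], as_index=False)[["count_methylated", "total"]]
                .sum()
            )
        per_sample[sample_id] = df
    unknown = [s for s in per_sample if s not in group_map]
    if unknown:
        raise ValueError(f"samples missing from group map: {unknown}")
    key = None
    for sample_id, df in per_sample.items():
        d = df.rename(
            columns={"count_methylated": f"m::{sample_id}", "total": f"t::{sample_id}"}
        )
        key = d if key is None else key.merge(d, on=["chrom", "start"], how="outer")
    key = key.fillna(0).sort_values(["chrom", "start"]).reset_index(drop=True)
    samples = list(per_sample)
    meth = key[[f"m::{s}" for s in samples]].to_numpy(int)
    total = key[[f"t::{s}" for s in samples]].to_numpy(int)
    return CpGMethylationMatrix(
        chrom=key["chrom"].to_numpy(object),
        pos=key["start"].to_numpy(int),
        meth=meth,
        total=total,
        samples=samples,
        groups=[group_map[s] for s in samples],
    )


def filter_cpgs(
    matrix: CpGMethylationMatrix, min_reads: int = 3, min_samples: int = 2
) -> CpGMethylationMatrix:
    """Keep CpGs covered by >= min_reads in >= min_samples samples."""
    keep = (matrix.total >= min_reads).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            f"no CpG covered with >= {min_reads} reads in >= {min_samples} samples"
        )
    return matrix.subset(keep)


def detect_candidate_regions(
    matrix: CpGMethylationMatrix, min_diff: float = 0.1, max_gap_bp: int = 1000
) -> pd.DataFrame:
    """Maximal runs of neighbouring CpGs with a consistent pha - aha sign.

    A CpG qualifies when |pooled pha - pooled aha| >= min_diff with coverage
    in both uniparental groups. Qualifying CpGs are chained while they share
    the chromosome and difference sign and lie within max_gap_bp of the
    previous qualifying CpG; a qualifying CpG of opposite sign breaks the
    chain. Non-qualifying CpGs between chained ones are spanned (the region
    statistic later uses every CpG in [i0, i1)). Returns one row per region
    with the contiguous CpG index range [i0, i1).
    """
    lev_a = matrix.pooled_level("aha")
    lev_p = matrix.pooled_level("pha")
    diff = lev_p - lev_a
    valid = np.isfinite(diff) & (np.abs(diff) >= min_diff)
    sign = np.sign(diff)
    n = matrix.n_cpgs
    cols = ["chrom", "start", "end", "i0", "i1", "n_cpgs", "sign"]
    if n == 0 or not valid.any():
        return pd.DataFrame(columns=cols)
    q = np.flatnonzero(valid)
    chain = (
        (matrix.chrom[q[1:]] == matrix.chrom[q[:-1]])
        & (sign[q[1:]] == sign[q[:-1]])
        & ((matrix.pos[q[1:]] - matrix.pos[q[:-1]]) <= max_gap_bp)
    )
    bounds = np.concatenate([[0], np.flatnonzero(~chain) + 1, [len(q)]])
    rows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        i0, i1 = int(q[a]), int(q[b - 1]) + 1
        rows.append(
            {
                "chrom": matrix.chrom[i0],
                "start": int(matrix.pos[i0]),
                "end": int(matrix.pos[i1 - 1]) + 1,
                "i0": i0,
                "i1": i1,
                "n_cpgs": i1 - i0,
                "sign": int(sign[i0]),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def _region_sample_sums(matrix: CpGMethylationMatrix, regions: pd.DataFrame):
    """(regions, samples) methylated and total counts via prefix sums."""
    cs_m = np.vstack([np.zeros((1, matrix.meth.shape[1])), np.cumsum(matrix.meth, axis=0)])
    cs_t = np.vstack([np.zeros((1, matrix.total.shape[1])), np.cumsum(matrix.total, axis=0)])
    i0 = regions["i0"].to_numpy()
    i1 = regions["i1"].to_numpy()
    return cs_m[i1] - cs_m[i0], cs_t[i1] - cs_t[i0]


def _labeling_stats(tvals: np.ndarray, weights: np.ndarray, idx_a, idx_p) -> np.ndarray:
    """Standardised coverage-weighted difference of arcsine levels, 'pha' - 'aha'.

    The arcsine-sqrt transform gives each sample's region level sampling
    variance ~ 1/(4 * coverage); with coverage weights the group-mean
    difference has variance 1/(4 T_pha) + 1/(4 T_aha) (T = group coverage),
    so dividing by that square root makes statistics comparable across
    regions of different size and depth, which the pooled null requires.
    """

    def wmean_and_cov(idx):
        w = weights[:, idx]
        x = tvals[:, idx]
        ok = np.isfinite(x) & (w > 0)
        wsum = np.where(ok, w, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(ok, w * x, 0).sum(axis=1) / np.maximum(wsum, 1e-12)
        return mean, wsum

    mean_p, t_p = wmean_and_cov(list(idx_p))
    mean_a, t_a = wmean_and_cov(list(idx_a))
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(1.0 / (4.0 * np.maximum(t_p, 1e-12)) + 1.0 / (4.0 * np.maximum(t_a, 1e-12)))
        z = (mean_p - mean_a) / se
    return np.where((t_p > 0) & (t_a > 0), z, np.nan)


def score_and_test_regions(
    regions: pd.DataFrame,
    matrix: CpGMethylationMatrix,
    n_perm: int | None = None,
) -> pd.DataFrame:
    """Permutation test of candidate regions.

    The statistic is the coverage-weighted mean difference of per-sample
    arcsine-sqrt-transformed region methylation, pha minus aha. The null
    pools the statistic over all mixed relabelings of the uniparental
    replicates (identity and the full aha<->pha swap excluded; the swap only
    negates the statistic) across all regions; with two replicates per group
    the per-region permutation distribution would be degenerate, pooling is
    what gives resolution. p = (1 + #{|null| >= |stat|}) / (1 + N), then BH.
    """
    out = regions.copy()
    if len(out) == 0:
        for col in ("stat", "p", "padj"):
            out[col] = np.array([], dtype=float)
        return out
    msum, tsum = _region_sample_sums(matrix, out)
    with np.errstate(invalid="ignore", divide="ignore"):
        lev = np.where(tsum > 0, msum / np.maximum(tsum, 1), np.nan)
    tvals = np.arcsin(np.sqrt(np.clip(lev, 0, 1)))
    idx_a = list(matrix.sample_indices("aha"))
    idx_p = list(matrix.sample_indices("pha"))
    if len(idx_a) < 2 or len(idx_p) < 2:
        raise ValueError("need >= 2 replicates per uniparental group")
    uni = idx_a + idx_p
    stat = _labeling_stats(tvals, tsum, idx_a, idx_p)

    relabelings = []
    for combo in itertools.combinations(uni, len(idx_p)):
        s = set(combo)
        if s == set(idx_p) or s == set(idx_a):
            continue  # identity / pure swap
        relabelings.append((sorted(set(uni) - s), sorted(s)))
    if n_perm is not None and n_perm < len(relabelings):
        relabelings = relabelings[:n_perm]
    null = np.concatenate(
        [np.abs(_labeling_stats(tvals, tsum, a, p)) for a, p in relabelings]
    )
    null = null[np.isfinite(null)]
    null.sort()
    n_null = len(null)
    n_ge = n_null - np.searchsorted(null, np.abs(stat), side="left")
    p = (1.0 + n_ge) / (1.0 + n_null)
    p = np.where(np.isfinite(stat), p, np.nan)
    out["stat"] = stat
    out["p"] = p
    out["padj"] = st.bh_adjust(p)
    return out


def filter_dmrs(
    regions: pd.DataFrame,
    matrix: CpGMethylationMatrix,
    fdr: float = 0.1,
    min_diff_pp: float = 30.0,
    min_beta: float = 0.25,
    min_len: int = 100,
    min_cov: int = 100,
    beta_scale: str = "allelic",
    coverage_groups: Sequence[str] = ("aha", "pha", "icsi"),
) -> pd.DataFrame:
    """Apply the six-filter cascade and emit DMRs with parental direction.

    Filters: BH-adjusted p <= fdr; ICSI strictly between aha and pha;
    total coverage >= min_cov summed over ``coverage_groups`` replicates;
    length >= min_len; |aha - pha| >= min_diff_pp percentage points;
    |beta_aha| and |beta_pha| >= min_beta. All six are re-asserted on the
    emitted frame.
    """
    if beta_scale not in ("allelic", "mixture"):
        raise ValueError("beta_scale must be 'allelic' or 'mixture'")
    out = regions.copy()
    if len(out) == 0:
        return out.assign(
            mean_aha=[], mean_pha=[], mean_icsi=[], diff_pp=[], beta_aha=[],
            beta_pha=[], coverage=[], length=[], parent=[],
        )
    msum, tsum = _region_sample_sums(matrix, out)
    groups = np.asarray(matrix.groups)

    def group_mean(name):
        idx = np.flatnonzero(groups == name)
        m = msum[:, idx].sum(axis=1)
        t = tsum[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, m / np.maximum(t, 1), np.nan)

    mean_aha = group_mean("aha")
    mean_pha = group_mean("pha")
    mean_icsi = group_mean("icsi")
    scale = 2.0 if beta_scale == "allelic" else 1.0
    beta_aha = scale * (mean_aha - mean_icsi)
    beta_pha = scale * (mean_pha - mean_icsi)
    cov_idx = np.flatnonzero(np.isin(groups, list(coverage_groups)))
    coverage = tsum[:, cov_idx].sum(axis=1)
    length = out["end"].to_numpy() - out["start"].to_numpy()
    diff_pp = 100.0 * np.abs(mean_pha - mean_aha)

    intermediate = ((mean_aha > mean_icsi) & (mean_icsi > mean_pha)) | (
        (mean_aha < mean_icsi) & (mean_icsi < mean_pha)
    )
    padj = out["padj"].to_numpy()
    keep = (
        ~np.isnan(padj)
        & (padj <= fdr)
        & intermediate
        & (coverage >= min_cov)
        & (length >= min_len)
        & (diff_pp >= min_diff_pp)
        & (np.abs(beta_aha) >= min_beta)
        & (np.abs(beta_pha) >= min_beta)
    )
    out["mean_aha"] = mean_aha
    out["mean_pha"] = mean_pha
    out["mean_icsi"] = mean_icsi
    out["diff_pp"] = diff_pp
    out["beta_aha"] = beta_aha
    out["beta_pha"] = beta_pha
    out["coverage"] = coverage.astype(int)
    out["length"] = length.astype(int)
    out = out[keep].reset_index(drop=True)
    out["parent"] = np.where(out["mean_pha"] > out["mean_aha"], "maternal", "paternal")
    out["dmr_id"] = [f"DMR{i:04d}" for i in range(len(out))]
    _assert_six_filters(out, fdr, min_diff_pp, min_beta, min_len, min_cov)
    return out


def _assert_six_filters(dmrs, fdr, min_diff_pp, min_beta, min_len, min_cov) -> None:
    """Post-hoc guarantee that every emitted DMR passes all printed filters."""
    if len(dmrs) == 0:
        return
    assert (dmrs["padj"] <= fdr).all()
    assert (dmrs["coverage"] >= min_cov).all()
    assert (dmrs["length"] >= min_len).all()
    assert (dmrs["diff_pp"] >= min_diff_pp).all()
    assert (dmrs["beta_aha"].abs() >= min_beta).all()
    assert (dmrs["beta_pha"].abs() >= min_beta).all()
    inter = (
        (dmrs["mean_aha"] > dmrs["mean_icsi"]) & (dmrs["mean_icsi"] > dmrs["mean_pha"])
    ) | ((dmrs["mean_aha"] < dmrs["mean_icsi"]) & (dmrs["mean_icsi"] < dmrs["mean_pha"]))
    assert inter.all()


def classify_dmr_origin(
    dmrs: pd.DataFrame,
    gamete_matrix: CpGMethylationMatrix,
    hi: float = 0.5,
    lo: float = 0.2,
    mid: float = 0.2,
) -> pd.DataFrame:
    """Gamete-origin class per DMR from oocyte/sperm methylation.

    Maternal DMRs: oocyte >= hi and sperm <= lo -> C2 (oocyte-specific);
    oocyte - sperm >= mid with sperm > lo -> C3 (oocyte-biased); both
    gametes >= hi -> C4 (established during preimplantation by paternal
    demethylation); both <= lo -> C1. Paternal DMRs: sperm >= hi and
    oocyte <= lo -> C5; both >= hi -> C4; both <= lo -> C1. DMRs without
    gamete coverage stay unassigned.
    """
    out = dmrs.copy()
    oo_level = np.full(len(out), np.nan)
    sp_level = np.full(len(out), np.nan)
    groups = np.asarray(gamete_matrix.groups)
    for j, (name, levels) in enumerate((("oocyte", oo_level), ("sperm", sp_level))):
        idx = np.flatnonzero(groups == name)
        if len(idx) == 0:
            continue
        for r, row in enumerate(out.itertuples()):
            on_chrom = gamete_matrix.chrom == row.chrom
            lo_i, hi_i = np.searchsorted(
                gamete_matrix.pos[on_chrom], [row.start, row.end]
            )
            sub = np.flatnonzero(on_chrom)[lo_i:hi_i]
            m = gamete_matrix.meth[np.ix_(sub, idx)].sum()
            t = gamete_matrix.total[np.ix_(sub, idx)].sum()
            if t > 0:
                levels[r] = m / t
    origin = np.full(len(out), "unassigned", dtype=object)
    for r in range(len(out)):
        oo, sp = oo_level[r], sp_level[r]
        if np.isnan(oo) or np.isnan(sp):
            continue
        if out["parent"].iloc[r] == "maternal":
            if oo >= hi and sp <= lo:
                origin[r] = "C2_oocyte_specific"
            elif oo - sp >= mid and sp > lo:
                origin[r] = "C3_oocyte_biased"
            elif oo >= hi and sp >= hi:
                origin[r] = "C4_preimplantation_established"
            elif oo <= lo and sp <= lo:
                origin[r] = "C1_gamete_unmethylated"
        else:
            if sp >= hi and oo <= lo:
                origin[r] = "C5_sperm_methylated"
            elif oo >= hi and sp >= hi:
                origin[r] = "C4_preimplantation_established"
            elif oo <= lo and sp <= lo:
                origin[r] = "C1_gamete_unmethylated"
    out["meth_oocyte"] = oo_level
    out["meth_sperm"] = sp_level
    out["origin_class"] = origin
    return out


def recover_known_regions(dmrs: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Overlap bookkeeping of emitted DMRs against labelled reference regions.

    One row per reference region: whether any DMR overlaps it by >= 1 bp and
    whether an overlapping DMR matches its parental direction. The summary
    recall is attached as frame attrs.
    """
    rows = []
    for ref in reference.itertuples():
        sub = dmrs[dmrs["chrom"] == ref.chrom]
        ov = sub[(sub["start"] < ref.end) & (sub["end"] > ref.start)]
        recovered = len(ov) > 0
        parent_match = bool(
            hasattr(ref, "parent") and recovered and (ov["parent"] == ref.parent).any()
        )
        rows.append(
            {
                "ref_id": getattr(ref, "dmr_id", getattr(ref, "name", str(ref.Index))),
                "chrom": ref.chrom,
                "start": ref.start,
                "end": ref.end,
                "recovered": recovered,
                "parent_match": parent_match,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["recall"] = float(out["recovered"].mean()) if len(out) else np.nan
    out.attrs["recall_parent"] = float(out["parent_match"].mean()) if len(out) else np.nan
    return out


def call_dmrs(
    matrix: CpGMethylationMatrix,
    min_reads: int = 3,
    min_samples: int = 2,
    min_diff: float = 0.1,
    max_gap_bp: int = 1000,
    n_perm: int | None = None,
    classify_origin: bool = True,
    **filter_kw,
) -> pd.DataFrame:
    """Full cascade: CpG filter -> candidates -> permutation test -> filters."""
    filtered = filter_cpgs(matrix, min_reads=min_reads, min_samples=min_samples)
    regions = detect_candidate_regions(filtered, min_diff=min_diff, max_gap_bp=max_gap_bp)
    tested = score_and_test_regions(regions, filtered, n_perm=n_perm)
    dmrs = filter_dmrs(tested, filtered, **filter_kw)
    if classify_origin and "oocyte" in matrix.groups and "sperm" in matrix.groups:
        dmrs = classify_dmr_origin(dmrs, matrix)
    return dmrs
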