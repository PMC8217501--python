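"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the shapes of the real study inputs: allele-resolved
RNA-seq counts from reciprocal B6 x cast blastocyst crosses, micro-WGBS
methylomes of androgenetic (aha), parthenogenetic (pha) and biparental (ICSI)
blastocysts plus gamete methylomes, H3K27me3 peak sets, TAD intervals, a gene
annotation, and matched WT/maternal-KO allelic count tables.

Planted truth (which genes are imprinted and toward which parent, where the
DMRs are and their gametic origin, which genes carry allele-specific
H3K27me3, which genes depend on which maternal regulator) is returned in a
:class:`SimTruth` and never leaks into the observables except through the
stochastic model itself.

Conventions: coordinates are 0-based half-open; cross directions are
"BxC" (B6 mother, forward) and "CxB" (cast mother, reverse); maternal
fraction always refers to reads from the maternal allele.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_allelic_counts",
    "simulate_methylomes",
    "simulate_intervals",
    "simulate_ko_counts",
]

GENE_CLASSES = ("biallelic", "maternal_imprint", "paternal_imprint", "skewed")
DEPENDENCE_CLASSES = ("mDnmt3l", "mEed", "both", "neither")
REGULATORS = ("mDnmt3l", "mEed")

# gamete methylation levels implied by each planted origin class; the
# downstream classifier's rule thresholds (hi=0.5, lo=0.2, mid=0.2) sit well
# inside the gaps between these levels.
_ORIGIN_GAMETE_LEVELS = {
    "C1_gamete_unmethylated": (0.05, 0.05),       # (oocyte, sperm)
    "C2_oocyte_specific": (0.85, 0.05),
    "C3_oocyte_biased": (0.60, 0.30),
    "C4_preimplantation_established": (0.85, 0.85),
    "C5_sperm_methylated": (0.05, 0.85),
}
_MATERNAL_ORIGIN = ("C2_oocyte_specific", "C3_oocyte_biased",
                    "C4_preimplantation_established", "C1_gamete_unmethylated")
_MATERNAL_ORIGIN_P = (0.40, 0.15, 0.40, 0.05)
_PATERNAL_ORIGIN = ("C5_sperm_methylated", "C4_preimplantation_established",
                    "C1_gamete_unmethylated")
_PATERNAL_ORIGIN_P = (0.76, 0.19, 0.05)


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with study-condition defaults."""

    seed: int = 0
    # --- allelic expression ---
    n_genes: int = 2000
    n_samples_per_cross: int = 4
    frac_imprinted_paternal: float = 0.025
    frac_imprinted_maternal: float = 0.025
    frac_skewed: float = 0.02
    mean_snp_reads: float = 200.0
    extra_reads_mean: float = 200.0       # non-SNP reads over disjoint exons
    dispersion: float = 0.05              # beta-binomial rho
    allelic_ratio_imprinted: float = 0.9  # major-allele fraction for imprints
    skew_ratio: float = 0.7               # B6-allele fraction for strain skew
    # --- genome / intervals ---
    genome: tuple[tuple[str, int], ...] = (("chr1", 50_000_000), ("chr2", 50_000_000))
    n_tads: int = 100
    n_peaks: int = 200
    peak_gene_frac: float = 0.8           # planted imprints given an ICM peak
    promoter_half_width: int = 2000
    # --- methylomes ---
    n_cpgs: int = 20_000
    n_planted_dmrs: int = 50
    dmr_length_bp: tuple[int, int] = (100, 500)
    dmr_meth_diff: tuple[float, float] = (0.30, 0.60)
    frac_dmr_maternal: float = 0.9
    baseline_meth: float = 0.25
    coverage_mean: float = 20.0
    # --- KO design ---
    ko_mean_reads: float = 500.0
    n_ko_samples: int = 4
    frac_dep_dnmt3l: float = 0.5   # among maternally expressed imprints
    frac_dep_eed: float = 0.35     # among paternally expressed imprints
    frac_dep_both: float = 0.10    # among paternally expressed imprints
    frac_dep_pat_dnmt3l: float = 0.20  # paternally expressed, methylation-dependent

    def __post_init__(self) -> None:
        fr = self.frac_imprinted_paternal + self.frac_imprinted_maternal + self.frac_skewed
        if not 0 <= fr <= 1:
            raise ValueError("planted gene fractions must lie in [0, 1] and sum to <= 1")
        if not 0 <= self.dispersion < 1:
            raise ValueError("dispersion rho must be in [0, 1)")
        for name in ("n_genes", "n_samples_per_cross", "n_cpgs", "n_tads", "n_peaks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_dmrs < 0:
            raise ValueError("n_planted_dmrs must be >= 0")
        if self.frac_dep_eed + self.frac_dep_both + self.frac_dep_pat_dnmt3l > 1:
            raise ValueError("paternal dependence fractions must sum to <= 1")
        self.dmr_length_bp = _as_range(self.dmr_length_bp)
        self.dmr_meth_diff = _as_range(self.dmr_meth_diff)
        self.genome = tuple((str(c), int(l)) for c, l in self.genome)

    def to_dict(self) -> dict:
        return asdict(self)


def _as_range(value) -> tuple:
    if np.isscalar(value):
        return (value, value)
    lo, hi = value
    if hi < lo:
        raise ValueError("range must be (low, high) with low <= high")
    return (lo, hi)


@dataclass
class SimTruth:
    """Planted ground truth, filled in by the generators that know it."""

    gene_labels: dict[str, str] = field(default_factory=dict)
    gene_parent: dict[str, str] = field(default_factory=dict)  # imprints only
    dmr_intervals: pd.DataFrame | None = None
    dependent_genes: dict[str, str] = field(default_factory=dict)
    k27_genes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "gene_labels": self.gene_labels,
            "gene_parent": self.gene_parent,
            "dependent_genes": self.dependent_genes,
            "k27_genes": self.k27_genes,
            "dmr_intervals": (
                self.dmr_intervals.to_dict(orient="records")
                if self.dmr_intervals is not None
                else None
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        dmrs = payload.get("dmr_intervals")
        return cls(
            gene_labels=payload.get("gene_labels", {}),
            gene_parent=payload.get("gene_parent", {}),
            dependent_genes=payload.get("dependent_genes", {}),
            k27_genes=payload.get("k27_genes", []),
            dmr_intervals=pd.DataFrame(dmrs) if dmrs else None,
        )


# ---------------------------------------------------------------------------
# shared deterministic placements


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def gene_ids(config: SimConfig) -> list[str]:
    return [f"gene{i:05d}" for i in range(config.n_genes)]


def _gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Strand-aware gene placement, identical for every op that needs it."""
    rng = _rng(config, 101)
    chroms = np.array([c for c, _ in config.genome])
    lengths = np.array([l for _, l in config.genome], dtype=float)
    probs = lengths / lengths.sum()
    idx = rng.choice(len(chroms), size=config.n_genes, p=probs)
    body_len = np.clip(
        rng.lognormal(mean=np.log(20_000), sigma=0.8, size=config.n_genes), 1_000, 200_000
    ).astype(int)
    tss = np.array(
        [rng.integers(body_len[i] + 1, lengths[idx[i]] - body_len[i] - 1)
         for i in range(config.n_genes)]
    )
    strand = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    start = np.where(strand == "+", tss, tss - body_len)
    end = np.where(strand == "+", tss + body_len, tss + 1)
    return pd.DataFrame(
        {
            "gene": gene_ids(config),
            "chrom": chroms[idx],
            "strand": strand,
            "tss": tss,
            "start": start,
            "end": end,
            "is_cpg_island_promoter": rng.random(config.n_genes) < 0.6,
        }
    )


def _gene_classes(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic class assignment and KO dependence labels per gene."""
    rng = _rng(config, 102)
    n = config.n_genes
    n_pat = int(round(config.frac_imprinted_paternal * n))
    n_mat = int(round(config.frac_imprinted_maternal * n))
    n_skew = int(round(config.frac_skewed * n))
    labels = np.array(["biallelic"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_pat]] = "paternal_imprint"
    labels[order[n_pat:n_pat + n_mat]] = "maternal_imprint"
    labels[order[n_pat + n_mat:n_pat + n_mat + n_skew]] = "skewed"

    dep = np.array(["neither"] * n, dtype=object)
    u = rng.random(n)
    pat = labels == "paternal_imprint"
    mat = labels == "maternal_imprint"
    # paternally expressed imprints may depend on maternal H3K27me3 (Eed),
    # maternal DNA methylation (Dnmt3l), or both; maternally expressed ones
    # only on maternal DNA methylation.
    e, b, d = config.frac_dep_eed, config.frac_dep_both, config.frac_dep_pat_dnmt3l
    dep[pat & (u < e)] = "mEed"
    dep[pat & (u >= e) & (u < e + b)] = "both"
    dep[pat & (u >= e + b) & (u < e + b + d)] = "mDnmt3l"
    dep[mat & (u < config.frac_dep_dnmt3l)] = "mDnmt3l"
    return labels, dep


def _maternal_fraction(labels: np.ndarray, cross: np.ndarray, config: SimConfig) -> np.ndarray:
    """(genes, samples) expected maternal fraction given class and cross.

    Imprinted genes keep the same parental orientation in both crosses;
    strain-skewed genes follow the B6 allele, so their maternal fraction
    flips between forward (B6 mother) and reverse (cast mother) crosses.
    """
    r = config.allelic_ratio_imprinted
    s = config.skew_ratio
    n_s = len(cross)
    frac = np.full((len(labels), n_s), 0.5)
    fwd = (cross == "BxC")[None, :]
    frac[labels == "maternal_imprint", :] = r
    frac[labels == "paternal_imprint", :] = 1.0 - r
    skew = labels == "skewed"
    frac[skew, :] = np.where(fwd, s, 1.0 - s)
    return frac


def _betabinom(rng: np.random.Generator, t: np.ndarray, p: np.ndarray, rho: float) -> np.ndarray:
    if rho <= 0:
        return rng.binomial(t, p)
    k = 1.0 / rho - 1.0
    lam = rng.beta(np.maximum(p * k, 1e-9), np.maximum((1 - p) * k, 1e-9))
    return rng.binomial(t, lam)


# ---------------------------------------------------------------------------
# operations


def simulate_allelic_counts(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Allelic count table for reciprocal-cross blastocysts.

    Returns a long-format table with one row per (gene, sample) carrying
    maternal/paternal SNP-spanning read counts, total disjoint-exon reads,
    cross direction and chromosome, plus the planted truth.
    """
    rng = _rng(config, 103)
    labels, dep = _gene_classes(config)
    ann = _gene_annotation(config)
    genes = ann["gene"].to_numpy()
    n_f = n_r = config.n_samples_per_cross
    samples = [f"F{i+1}" for i in range(n_f)] + [f"R{i+1}" for i in range(n_r)]
    cross = np.array(["BxC"] * n_f + ["CxB"] * n_r)

    t = rng.poisson(config.mean_snp_reads, size=(config.n_genes, len(samples)))
    frac = _maternal_fraction(labels, cross, config)
    m = _betabinom(rng, t, frac, config.dispersion)
    total = t + rng.poisson(config.extra_reads_mean, size=t.shape)

    table = pd.DataFrame(
        {
            "gene": np.repeat(genes, len(samples)),
            "sample": np.tile(samples, config.n_genes),
            "cross": np.tile(cross, config.n_genes),
            "maternal_snp_reads": m.ravel(),
            "paternal_snp_reads": (t - m).ravel(),
            "total_reads": total.ravel(),
            "chrom": np.repeat(ann["chrom"].to_numpy(), len(samples)),
        }
    )
    parent = {}
    for g, lab in zip(genes, labels):
        if lab == "maternal_imprint":
            parent[g] = "maternal"
        elif lab == "paternal_imprint":
            parent[g] = "paternal"
    truth = SimTruth(
        gene_labels=dict(zip(genes, labels)),
        gene_parent=parent,
        dependent_genes={g: d for g, d in zip(genes, dep)},
    )
    return table, truth


def _place_dmrs(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping planted DMR intervals on the synthetic genome."""
    chroms = [c for c, _ in config.genome]
    lengths = {c: l for c, l in config.genome}
    lo, hi = config.dmr_length_bp
    dlo, dhi = config.dmr_meth_diff
    rows = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    probs = np.array([lengths[c] for c in chroms], float)
    probs /= probs.sum()
    attempts = 0
    while len(rows) < config.n_planted_dmrs:
        attempts += 1
        if attempts > 100 * max(1, config.n_planted_dmrs):
            raise ValueError("could not place non-overlapping planted DMRs; genome too small")
        c = chroms[rng.choice(len(chroms), p=probs)]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(10_000, lengths[c] - length - 10_000))
        end = start + length
        # keep a 2 kb guard band so flanking CpGs never join two planted DMRs
        if any(start - 2000 < e and end + 2000 > s for s, e in occupied[c]):
            continue
        occupied[c].append((start, end))
        parent = "maternal" if rng.random() < config.frac_dmr_maternal else "paternal"
        if parent == "maternal":
            origin = str(rng.choice(_MATERNAL_ORIGIN, p=_MATERNAL_ORIGIN_P))
        else:
            origin = str(rng.choice(_PATERNAL_ORIGIN, p=_PATERNAL_ORIGIN_P))
        diff = float(rng.uniform(dlo, dhi))
        rows.append(
            {
                "dmr_id": f"planted{len(rows):03d}",
                "chrom": c,
                "start": start,
                "end": end,
                "parent": parent,
                "meth_diff": diff,
                "origin_class": origin,
            }
        )
    return pd.DataFrame(rows)


def simulate_methylomes(config: SimConfig, truth: SimTruth | None = None):
    """Per-CpG methylation counts for aha/pha/ICSI blastocysts and gametes.

    CpG positions are clustered: planted DMRs are CpG-dense (as germline DMRs
    are), half of the remaining CpGs sit in background islands, the rest are
    scattered. Outside planted DMRs every blastocyst group sits at the global
    baseline (~25% methylation); inside a planted maternal DMR pha gains the
    planted difference, aha stays at baseline and ICSI is exactly their
    midpoint (a biparental methylome averages the two parental alleles).

    Returns (CpGMethylationMatrix, SimTruth).
    """
    from .dmr import CpGMethylationMatrix

    rng = _rng(config, 104)
    dmrs = _place_dmrs(config, rng)
    chroms = [c for c, _ in config.genome]
    lengths = {c: l for c, l in config.genome}

    pos_by_chrom: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
    planted_cpg = 0
    for row in dmrs.itertuples():
        spacing = int(rng.integers(20, 41))
        pos = np.arange(row.start, row.end, spacing)
        if pos[-1] != row.end - 1:  # anchor the last CpG at the DMR edge
            pos = np.append(pos, row.end - 1)
        pos_by_chrom[row.chrom].append(pos)
        planted_cpg += len(pos)
    remaining = max(0, config.n_cpgs - planted_cpg)
    n_island_cpg = remaining // 2
    n_islands = max(1, n_island_cpg // 10)
    total_len = sum(lengths.values())
    for _ in range(n_islands):
        c = chroms[rng.choice(len(chroms), p=np.array([lengths[x] for x in chroms]) / total_len)]
        start = int(rng.integers(5_000, lengths[c] - 5_000))
        pos = start + np.arange(10) * int(rng.integers(20, 41))
        pos_by_chrom[c].append(pos)
    n_scatter = remaining - n_islands * 10
    for c in chroms:
        k = int(round(n_scatter * lengths[c] / total_len))
        pos_by_chrom[c].append(rng.integers(0, lengths[c], size=max(k, 0)))

    chrom_arr, pos_arr = [], []
    for c in chroms:
        pos = np.unique(np.concatenate(pos_by_chrom[c])) if pos_by_chrom[c] else np.array([], int)
        pos_arr.append(pos)
        chrom_arr.append(np.full(len(pos), c, dtype=object))
    pos_all = np.concatenate(pos_arr)
    chrom_all = np.concatenate(chrom_arr)
    n = len(pos_all)

    base = config.baseline_meth
    level = {
        "aha": np.full(n, base),
        "pha": np.full(n, base),
        "icsi": np.full(n, base),
        "oocyte": np.full(n, 0.35),
        "sperm": np.full(n, 0.75),
    }
    # background islands (incl. planted positions, overwritten below) keep
    # blastocyst baseline; gamete islands are hypomethylated
    for row in dmrs.itertuples():
        mask = (chrom_all == row.chrom) & (pos_all >= row.start) & (pos_all < row.end)
        hi_level = min(base + row.meth_diff, 0.98)
        if row.parent == "maternal":
            level["pha"][mask] = hi_level
            level["aha"][mask] = base
        else:
            level["aha"][mask] = hi_level
            level["pha"][mask] = base
        level["icsi"][mask] = (level["aha"][mask] + level["pha"][mask]) / 2.0
        oo, sp = _ORIGIN_GAMETE_LEVELS[row.origin_class]
        level["oocyte"][mask] = oo
        level["sperm"][mask] = sp

    samples, groups, meth_cols, total_cols = [], [], [], []
    for group, reps in (("aha", 2), ("pha", 2), ("icsi", 2), ("oocyte", 1), ("sperm", 1)):
        for r in range(1, reps + 1):
            depth = rng.poisson(config.coverage_mean, size=n)
            meth = rng.binomial(depth, level[group])
            samples.append(f"{group}_{r}")
            groups.append(group)
            meth_cols.append(meth)
            total_cols.append(depth)

    matrix = CpGMethylationMatrix(
        chrom=chrom_all,
        pos=pos_all,
        meth=np.column_stack(meth_cols),
        total=np.column_stack(total_cols),
        samples=samples,
        groups=groups,
    )
    out_truth = truth if truth is not None else SimTruth()
    out_truth.dmr_intervals = dmrs
    return matrix, out_truth


def simulate_intervals(config: SimConfig, truth: SimTruth | None = None):
    """TADs tiling the genome, H3K27me3 peak sets and the gene annotation.

    If ``truth`` carries planted gene labels, a configurable fraction of the
    paternally expressed imprints receives a maternal ICM H3K27me3 peak (and
    an oocyte-specific peak) within 5 kb of its TSS, emulating non-canonical
    imprints; the peak-marked genes are recorded in the truth.
    """
    rng = _rng(config, 105)
    ann = _gene_annotation(config)

    tad_rows = []
    lengths = np.array([l for _, l in config.genome], float)
    for (chrom, length), n_c in zip(
        config.genome,
        np.maximum(1, np.round(config.n_tads * lengths / lengths.sum()).astype(int)),
    ):
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_c - 1, replace=False)) if n_c > 1 else np.array([], int)
        bounds = np.concatenate([[0], cuts, [length]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            tad_rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                             "score": float(np.round(rng.uniform(0.2, 1.0), 3))})
    tads = pd.DataFrame(tad_rows)

    peak_sets: dict[str, list[dict]] = {
        k: [] for k in ("ICM_maternal", "ICM_paternal", "ICM_all", "oocyte", "sperm")
    }
    for name in peak_sets:
        for _ in range(config.n_peaks):
            c, length = config.genome[rng.choice(len(config.genome))]
            w = int(rng.integers(2_000, 10_000))
            s = int(rng.integers(0, length - w))
            peak_sets[name].append({"chrom": c, "start": s, "end": s + w})

    k27_genes: list[str] = []
    if truth is not None and truth.gene_labels:
        ann_idx = ann.set_index("gene")
        for g, lab in truth.gene_labels.items():
            if lab != "paternal_imprint" or rng.random() >= config.peak_gene_frac:
                continue
            row = ann_idx.loc[g]
            offset = int(rng.integers(-4_000, 1_000))
            s = max(0, int(row["tss"]) + offset)
            peak = {"chrom": row["chrom"], "start": s, "end": s + 3_000}
            peak_sets["ICM_maternal"].append(peak)
            peak_sets["ICM_all"].append(dict(peak))
            peak_sets["oocyte"].append(dict(peak))
            k27_genes.append(g)

    peaks = {
        name: pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
        for name, rows in peak_sets.items()
    }
    out_truth = truth if truth is not None else SimTruth()
    out_truth.k27_genes = sorted(k27_genes)
    return peaks, tads, ann


def simulate_ko_counts(
    config: SimConfig, truth: SimTruth, regulator: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched WT and maternal-KO allelic count tables for one regulator.

    WT samples reproduce each gene's planted parental bias; in the KO table,
    genes whose planted dependence includes ``regulator`` revert to a 0.5
    maternal fraction. Marginal (allele-summed) expression is drawn from the
    same distribution in both genotypes.
    """
    if regulator not in REGULATORS:
        raise ValueError(f"unknown regulator {regulator!r}; expected one of {REGULATORS}")
    if not truth.dependent_genes:
        raise ValueError("truth carries no dependence labels; run simulate_allelic_counts first")
    rng = _rng(config, 106 + REGULATORS.index(regulator))
    ann = _gene_annotation(config)
    genes = ann["gene"].to_numpy()
    labels = np.array([truth.gene_labels[g] for g in genes], dtype=object)
    dep = np.array([truth.dependent_genes[g] for g in genes], dtype=object)

    n_s = config.n_ko_samples
    cross = np.array(["BxC"] * n_s)
    frac_wt = _maternal_fraction(labels, cross, config)
    affected = (dep == regulator) | (dep == "both")
    frac_ko = frac_wt.copy()
    frac_ko[affected, :] = 0.5

    out = []
    for cond, frac in (("WT", frac_wt), ("KO", frac_ko)):
        t = rng.poisson(config.ko_mean_reads, size=(config.n_genes, n_s))
        m = _betabinom(rng, t, frac, config.dispersion)
        total = t + rng.poisson(config.extra_reads_mean, size=t.shape)
        out.append(
            pd.DataFrame(
                {
                    "gene": np.repeat(genes, n_s),
                    "sample": np.tile([f"{cond}{i+1}" for i in range(n_s)], config.n_genes),
                    "cross": np.tile(cross, config.n_genes),
                    "maternal_snp_reads": m.ravel(),
                    "paternal_snp_reads": (t - m).ravel(),
                    "total_reads": total.ravel(),
                    "chrom": np.repeat(ann["chrom"].to_numpy(), n_s),
                    "dataset": regulator,
                }
            )
        )
    return out[0], out[1]
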