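"""Benchmark harness: recovery, calibration and symmetry metrics.

These routines run the pipeline on freshly simulated studies with planted
truth and measure how well each stage recovers it (classifier recall and
precision, DMR recall and empirical FDR, permutation-null calibration,
KO-dependence recovery). They back both the acceptance test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import allelic as al
from . import dependency as dep
from . import dmr as dm
from . import integrate as ig
from . import simulate as sim

__all__ = [
    "allelic_recovery",
    "equivalence_boundary_rejection",
    "equivalence_null_detection",
    "dmr_recovery",
    "dmr_label_swap_symmetric",
    "tad_null_calibration",
    "ko_dependence_recovery",
]


def _seed_stream(base_seed: int, salt: int, n: int) -> list[int]:
    """Independent child seeds below 2^31 derived from a base seed."""
    ss = np.random.SeedSequence([int(base_seed), int(salt)])
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def allelic_recovery(n_seeds: int = 50, base_seed: int = 0, **config_kw) -> dict:
    """BsX recall / parent accuracy / false-positive rate on planted imprints.

    Study conditions: 2,000 genes, 5% planted 90:10 imprints, mean 200 SNP
    reads, rho = 0.05, eight samples in reciprocal crosses.
    """
    recalls, accs, fprs = [], [], []
    for seed in _seed_stream(base_seed, 1, n_seeds):
        cfg = sim.SimConfig(seed=seed, **config_kw)
        table, truth = sim.simulate_allelic_counts(cfg)
        calls = al.analyze_allelic(table)
        called = calls[calls["bsx"]].set_index("gene")
        planted = {g for g, l in truth.gene_labels.items() if l.endswith("imprint")}
        biallelic = {g for g, l in truth.gene_labels.items() if l == "biallelic"}
        tp = planted & set(called.index)
        recalls.append(len(tp) / len(planted))
        if tp:
            accs.append(
                np.mean([called.loc[g, "parent"] == truth.gene_parent[g] for g in tp])
            )
        fprs.append(len(set(called.index) & biallelic) / len(biallelic))
    return {
        "recall": float(np.mean(recalls)),
        "parent_accuracy": float(np.mean(accs)),
        "false_bsx_rate": float(np.mean(fprs)),
        "n_seeds": n_seeds,
    }


def equivalence_boundary_rejection(
    n_genes: int = 1000, base_seed: int = 0, padj_max: float = 0.1
) -> float:
    """Rejection rate of the biallelic TOST at planted |log2FC| = 1.

    A maternal fraction of 2/3 puts every gene exactly on the equivalence
    margin, where the test's size must not exceed its level.
    """
    seed = _seed_stream(base_seed, 2, 1)[0]
    cfg = sim.SimConfig(
        seed=seed, n_genes=n_genes, frac_imprinted_maternal=1.0,
        frac_imprinted_paternal=0.0, frac_skewed=0.0,
        allelic_ratio_imprinted=2.0 / 3.0,
    )
    table, _ = sim.simulate_allelic_counts(cfg)
    res = al.test_equivalence(table)
    return float((res["padj_equiv"] <= padj_max).mean())


def equivalence_null_detection(
    n_genes: int = 1000, base_seed: int = 0, reads_per_sample: int = 500,
    padj_max: float = 0.1,
) -> float:
    """Power of the TOST to declare truly balanced, well-covered genes."""
    seed = _seed_stream(base_seed, 3, 1)[0]
    cfg = sim.SimConfig(
        seed=seed, n_genes=n_genes, frac_imprinted_maternal=0.0,
        frac_imprinted_paternal=0.0, frac_skewed=0.0,
        mean_snp_reads=float(reads_per_sample),
    )
    table, _ = sim.simulate_allelic_counts(cfg)
    res = al.test_equivalence(table)
    return float((res["padj_equiv"] <= padj_max).mean())


def dmr_recovery(n_seeds: int = 50, base_seed: int = 0, **config_kw) -> dict:
    """Planted-DMR recall and empirical FDR under the six printed filters.

    Study conditions: 20,000 CpGs, 50 planted 100-500 bp DMRs with 30-60 pp
    differences, depth 20. False positives are emitted DMRs overlapping no
    planted interval; FDR pools calls across seeds.
    """
    recalls = []
    n_fp = 0
    n_called = 0
    for seed in _seed_stream(base_seed, 4, n_seeds):
        cfg = sim.SimConfig(seed=seed, **config_kw)
        matrix, truth = sim.simulate_methylomes(cfg)
        dmrs = dm.call_dmrs(matrix, classify_origin=False)
        rec = dm.recover_known_regions(dmrs, truth.dmr_intervals)
        recalls.append(rec.attrs["recall"])
        n_called += len(dmrs)
        for d in dmrs.itertuples():
            planted = truth.dmr_intervals
            hit = (
                (planted["chrom"] == d.chrom)
                & (planted["start"] < d.end)
                & (planted["end"] > d.start)
            ).any()
            n_fp += int(not hit)
    return {
        "recall": float(np.mean(recalls)),
        "empirical_fdr": float(n_fp / max(n_called, 1)),
        "n_called": int(n_called),
        "n_seeds": n_seeds,
    }


def dmr_label_swap_symmetric(base_seed: int = 0, **config_kw) -> bool:
    """Exact parent flip and statistic negation under an aha/pha swap."""
    seed = _seed_stream(base_seed, 5, 1)[0]
    cfg = sim.SimConfig(seed=seed, **config_kw)
    matrix, _ = sim.simulate_methylomes(cfg)
    swap = {"aha": "pha", "pha": "aha"}
    swapped = dm.CpGMethylationMatrix(
        matrix.chrom.copy(), matrix.pos.copy(), matrix.meth.copy(),
        matrix.total.copy(), list(matrix.samples),
        [swap.get(g, g) for g in matrix.groups],
    )
    a = dm.call_dmrs(matrix, classify_origin=False)
    b = dm.call_dmrs(swapped, classify_origin=False)
    flip = {"maternal": "paternal", "paternal": "maternal"}
    return bool(
        len(a) == len(b)
        and np.array_equal(a["start"].to_numpy(), b["start"].to_numpy())
        and np.allclose(a["stat"].to_numpy(), -b["stat"].to_numpy(), atol=1e-12)
        and np.allclose(a["padj"].to_numpy(), b["padj"].to_numpy(), atol=1e-12)
        and (a["parent"].map(flip).to_numpy() == b["parent"].to_numpy()).all()
    )


def tad_null_calibration(
    n_reps: int = 200,
    n_shifts: int = 2000,
    base_seed: int = 0,
    n_genes: int = 300,
    n_dmrs: int = 60,
    n_tads: int = 60,
) -> dict:
    """Uniformity of the circular-shift empirical p under random placement.

    Genes, DMRs and TADs are placed independently and uniformly, so the
    observed co-occurrence count is exchangeable with its shifted versions
    and the empirical p-value must be (conservatively) uniform.
    """
    chroms = ("chr1", "chr2")
    L = 50_000_000
    pvals = []
    for seed in _seed_stream(base_seed, 6, n_reps):
        rng = np.random.default_rng(seed)
        tad_rows = []
        per_chrom = n_tads // len(chroms)
        for c in chroms:
            cuts = np.sort(
                rng.choice(np.arange(1, L), size=per_chrom - 1, replace=False)
            )
            bounds = np.concatenate([[0], cuts, [L]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                tad_rows.append(
                    {"chrom": c, "start": int(s), "end": int(e),
                     "score": float(rng.uniform(0.2, 1.0))}
                )
        tads = pd.DataFrame(tad_rows)
        ann = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n_genes)],
                "chrom": rng.choice(chroms, n_genes),
                "tss": rng.integers(0, L, n_genes),
            }
        )
        dmrs = pd.DataFrame(
            {
                "chrom": rng.choice(chroms, n_dmrs),
                "start": rng.integers(0, L - 1000, n_dmrs),
            }
        )
        dmrs["end"] = dmrs["start"] + 500
        dmrs["dmr_id"] = [f"d{i}" for i in range(n_dmrs)]
        res = ig.tad_cooccurrence_test(
            ann, dmrs, tads, n_shifts=n_shifts, seed=int(rng.integers(2**31 - 1))
        )
        pvals.append(res["empirical_p"])
    ks = sps.kstest(pvals, "uniform")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_reps": n_reps,
    }


def ko_dependence_recovery(n_seeds: int = 20, base_seed: int = 0, **config_kw) -> dict:
    """Dependence-class recall and precision on planted KO responses.

    A predicted positive counts as correct only when the class matches the
    planted one exactly (mDnmt3l / mEed / both).
    """
    n_tp = n_pred = n_true = 0
    for seed in _seed_stream(base_seed, 7, n_seeds):
        cfg = sim.SimConfig(seed=seed, **config_kw)
        _, truth = sim.simulate_allelic_counts(cfg)
        wt_d, ko_d = sim.simulate_ko_counts(cfg, truth, "mDnmt3l")
        wt_e, ko_e = sim.simulate_ko_counts(cfg, truth, "mEed")
        universe = sorted(truth.gene_parent)
        res = dep.analyze_dependency(wt_d, ko_d, wt_e, ko_e, universe)
        pred = res.set_index("gene")["dependence"]
        true = {g: truth.dependent_genes[g] for g in universe}
        pred_pos = {g for g in pred.index if pred[g] != "neither"}
        true_pos = {g for g, v in true.items() if v != "neither"}
        correct = {g for g in pred_pos & true_pos if pred[g] == true[g]}
        n_tp += len(correct)
        n_pred += len(pred_pos)
        n_true += len(true_pos)
    return {
        "recall": float(n_tp / max(n_true, 1)),
        "precision": float(n_tp / max(n_pred, 1)),
        "n_seeds": n_seeds,
    }
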