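"""Pipeline orchestration and summary bookkeeping.

``run_pipeline`` drives the full synthetic-study analysis from a single
config: generate inputs with planted truth, classify allelic expression,
call DMRs, integrate, test KO dependence, and write every stage's tables
plus a machine-readable run log. ``build_summary`` recomputes the headline
counts and fractions (category sizes, DMR-distance bins, TAD co-membership,
H3K27me3 status, DMR parent/origin composition) from stage outputs alone,
so re-running the report never changes numbers.
"""

from __future__ import annotations

import json
import os
import sys
import time
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import pandas as pd

from . import __version__
from . import allelic as al
from . import dependency as dep
from . import dmr as dm
from . import integrate as ig
from . import io as iomod
from . import simulate as sim

__all__ = ["summarize_fractions", "build_summary", "run_pipeline", "load_config"]


def summarize_fractions(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage as printed in the study: round half away from zero.

    (778, 859) -> 91; (5, 8) at one decimal -> 62.5.
    """
    if denominator == 0:
        raise ZeroDivisionError("denominator must be positive")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    value = float(q.quantize(exp, rounding=ROUND_HALF_UP))
    return value


GENE_GROUPS = ("all", "pubBsX", "published_unconfirmed", "equivalent", "nBiX", "nBsX")


def build_summary(
    calls: pd.DataFrame,
    dmrs: pd.DataFrame,
    associations: pd.DataFrame,
    dependencies: pd.DataFrame | None = None,
) -> dict:
    """Category-intersection tables from stage outputs.

    Per gene group: size, fraction with a DMR within 100/250 kb or 10 kb of
    the TSS, fraction sharing a TAD with a DMR, and H3K27me3 TSS status
    counts. Plus DMR counts by parent and gamete-origin class and, when KO
    results are given, dependence-class counts.
    """
    merged = calls.merge(associations, on="gene", how="left")
    groups: dict[str, pd.DataFrame] = {"all": merged}
    for g in GENE_GROUPS[1:]:
        groups[g] = merged[merged["novelty"] == g] if g not in ("equivalent",) else merged[
            merged["category"] == "equivalent"
        ]
    gene_rows = []
    for name, sub in groups.items():
        n = len(sub)
        row = {"group": name, "n_genes": n}
        for col in ("within_100kb", "within_250kb", "within_10kb_of_tss", "same_tad_dmr"):
            if col in sub and n:
                k = int(sub[col].fillna(False).sum())
                row[f"n_{col}"] = k
                row[f"pct_{col}"] = summarize_fractions(k, n)
            else:
                row[f"n_{col}"] = 0
                row[f"pct_{col}"] = 0.0
        if "k27_tss_status" in sub and n:
            for status in ("maternal", "paternal", "both", "none"):
                row[f"k27_{status}"] = int((sub["k27_tss_status"] == status).sum())
        gene_rows.append(row)
    gene_table = pd.DataFrame(gene_rows)

    dmr_rows = []
    n_dmr = len(dmrs)
    for parent in ("maternal", "paternal"):
        k = int((dmrs["parent"] == parent).sum()) if n_dmr else 0
        dmr_rows.append(
            {
                "slice": f"parent={parent}",
                "n": k,
                "pct": summarize_fractions(k, n_dmr) if n_dmr else 0.0,
            }
        )
    if "origin_class" in dmrs.columns:
        for oc, k in dmrs["origin_class"].value_counts().items():
            dmr_rows.append(
                {"slice": f"origin={oc}", "n": int(k),
                 "pct": summarize_fractions(int(k), n_dmr)}
            )
    dmr_table = pd.DataFrame(dmr_rows)

    out = {"genes": gene_table, "dmrs": dmr_table}
    if dependencies is not None and len(dependencies):
        out["dependence"] = (
            dependencies["dependence"].value_counts().rename_axis("dependence")
            .reset_index(name="n")
        )
    return out


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _log(quiet: bool, msg: str) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def run_pipeline(config: Mapping, outdir, quiet: bool = False) -> dict:
    """Run every stage on a simulated study and write all outputs.

    ``config`` holds a seed, optional SimConfig overrides under ``simulate``
    and optional threshold overrides under ``thresholds``. Outputs: stage
    TSVs, DMR BED, truth sidecar and a run log with versions, seed and
    thresholds. Any stage failure aborts with the failing stage named.
    """
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    sim_kw = dict(config.get("simulate", {}))
    thresholds = dict(config.get("thresholds", {}))
    cfg = sim.SimConfig(seed=seed, **sim_kw)
    stages: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                _log(quiet, f"[imprintscan] stage {name} ...")
                return self_

            def __exit__(self_, exc_type, exc, tb):
                stages[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Timer()

    with stage("simulate"):
        table, truth = sim.simulate_allelic_counts(cfg)
        matrix, truth = sim.simulate_methylomes(cfg, truth)
        peaks, tads, ann = sim.simulate_intervals(cfg, truth)
        iomod.write_allelic_counts(table, os.path.join(outdir, "allelic_counts.tsv"))
        iomod.write_annotation(ann, os.path.join(outdir, "annotation.tsv"))
        iomod.write_bed(tads, os.path.join(outdir, "tads.bed"), score_col="score")
        for name, df in peaks.items():
            iomod.write_bed(df, os.path.join(outdir, f"peaks_{name}.bed"))
        truth.to_json(os.path.join(outdir, "truth.json"))
        # a published-imprint list: planted imprints are "published" with
        # probability 1/2, plus a few unconfirmed decoys
        rng_pub = __import__("numpy").random.default_rng([seed, 201])
        imprinted = sorted(truth.gene_parent)
        published = [g for g in imprinted if rng_pub.random() < 0.5]
        decoys = [g for g, lab in sorted(truth.gene_labels.items())
                  if lab == "biallelic" and rng_pub.random() < 0.01]
        published = sorted(published + decoys)
        with open(os.path.join(outdir, "published_imprints.tsv"), "w") as fh:
            fh.write("\n".join(published) + "\n")

    with stage("allelic"):
        calls = al.analyze_allelic(table, published_genes=published)
        calls.drop(columns=["z"], errors="ignore").to_csv(
            os.path.join(outdir, "allelic_calls.tsv"), sep="\t", index=False
        )
        results["calls"] = calls

    with stage("dmr"):
        dmrs = dm.call_dmrs(matrix, **thresholds.get("dmr", {}))
        dmrs.to_csv(os.path.join(outdir, "dmrs.tsv"), sep="\t", index=False)
        if len(dmrs):
            bed = dmrs.assign(
                score=(-10 * __import__("numpy").log10(dmrs["padj"].clip(lower=1e-100)))
                .clip(upper=1000).round(1),
                strand=dmrs["parent"].map({"maternal": "+", "paternal": "-"}),
            )
            iomod.write_bed(bed, os.path.join(outdir, "dmrs.bed"),
                            score_col="score", name_col="dmr_id", strand_col="strand")
        results["dmrs"] = dmrs

    with stage("integrate"):
        integ = ig.integrate_all(
            calls, dmrs, ann, peaks, tads,
            n_shifts=int(thresholds.get("n_shifts", 2000)), seed=seed,
        )
        integ["associations"].to_csv(
            os.path.join(outdir, "associations.tsv"), sep="\t", index=False
        )
        integ["clusters"].to_csv(os.path.join(outdir, "clusters.tsv"), sep="\t", index=False)
        results["integration"] = integ

    with stage("depend"):
        wt_d, ko_d = sim.simulate_ko_counts(cfg, truth, "mDnmt3l")
        wt_e, ko_e = sim.simulate_ko_counts(cfg, truth, "mEed")
        universe = sorted(
            set(calls.loc[calls["bsx"], "gene"]) | set(published)
        )
        dependencies = dep.analyze_dependency(wt_d, ko_d, wt_e, ko_e, universe)
        dependencies.to_csv(os.path.join(outdir, "dependency.tsv"), sep="\t", index=False)
        results["dependencies"] = dependencies

    with stage("report"):
        summary = build_summary(calls, dmrs, integ["associations"], dependencies)
        for name, df in summary.items():
            df.to_csv(os.path.join(outdir, f"summary_{name}.tsv"), sep="\t", index=False)
        json_summary = {
            name: df.to_dict(orient="records") for name, df in summary.items()
        }
        json_summary["tad_test"] = {
            "observed": int(integ["tad_test"]["observed"]),
            "n_genes": int(integ["tad_test"]["n_genes"]),
            "empirical_p": float(integ["tad_test"]["empirical_p"]),
        }
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(json_summary, fh, indent=1)
        results["summary"] = summary

    run_log = {
        "imprintscan_version": __version__,
        "seed": seed,
        "sim_config": cfg.to_dict(),
        "thresholds": thresholds,
        "stage_seconds": stages,
    }
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(run_log, fh, indent=1)
    _log(quiet, f"[imprintscan] done; outputs in {outdir}")
    return results
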