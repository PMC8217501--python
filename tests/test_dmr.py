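"""DMR calling: parsing, candidate detection, permutation test, filters."""

import numpy as np
import pandas as pd
import pytest

from imprintscan import io as iomod
from imprintscan.dmr import (
    CpGMethylationMatrix,
    call_dmrs,
    classify_dmr_origin,
    detect_candidate_regions,
    filter_cpgs,
    filter_dmrs,
    read_methylation,
    recover_known_regions,
    score_and_test_regions,
)
from imprintscan.simulate import SimConfig, simulate_methylomes

from conftest import make_meth_matrix


def test_bismark_line_parsing(tmp_path):
    path = tmp_path / "s.cov"
    path.write_text("chr1\t100\t101\t75.0\t3\t1\n")
    df = iomod.read_bismark_coverage(path)
    assert df.iloc[0]["count_methylated"] == 3
    assert df.iloc[0]["total"] == 4  # percent column ignored, recomputed


def test_same_sample_files_summed_distinct_samples_kept(tmp_path):
    for name, counts in (("a1", (3, 1)), ("a2", (2, 2)), ("b", (5, 0))):
        (tmp_path / f"{name}.cov").write_text(
            f"chr1\t100\t101\t0\t{counts[0]}\t{counts[1]}\n"
        )
    files = [
        ("s1", tmp_path / "a1.cov"),
        ("s1", tmp_path / "a2.cov"),  # same sample id -> summed
        ("s2", tmp_path / "b.cov"),
    ]
    m = read_methylation(files, {"s1": "aha", "s2": "pha"})
    i1, i2 = m.samples.index("s1"), m.samples.index("s2")
    assert m.meth[0, i1] == 5 and m.total[0, i1] == 8
    assert m.meth[0, i2] == 5 and m.total[0, i2] == 5


def test_cpg_coverage_filter_rule():
    """At least three reads in at least two samples, as printed."""
    n = 3
    mat = CpGMethylationMatrix(
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=np.array([10, 20, 30]),
        meth=np.zeros((n, 6), dtype=int),
        total=np.array(
            [
                [3, 3, 0, 0, 0, 0],   # two samples at 3 -> kept
                [3, 2, 2, 2, 2, 2],   # only one sample reaches 3 -> removed
                [2, 2, 2, 2, 2, 2],   # none reaches 3 -> removed
            ]
        ),
        samples=[f"s{i}" for i in range(6)],
        groups=["aha", "aha", "pha", "pha", "icsi", "icsi"],
    )
    out = filter_cpgs(mat)
    assert list(out.pos) == [10]
    surviving = ((mat.total >= 3).sum(axis=1) >= 2).sum()
    assert out.n_cpgs == surviving  # brute-force scan agreement


def test_cpg_filter_empty_result_is_an_error():
    mat = make_meth_matrix([10], {g: [0.5] for g in ("aha", "pha", "icsi")}, depth=1)
    with pytest.raises(ValueError, match="no CpG"):
        filter_cpgs(mat, min_reads=3, min_samples=2)


def test_candidate_regions_run_and_sign_split():
    levels_a = np.array([0.1, 0.1, 0.1, 0.5, 0.5])
    levels_p = np.array([0.5, 0.5, 0.5, 0.1, 0.1])  # sign flips at CpG 4
    pos = [100, 150, 200, 260, 320]
    mat = make_meth_matrix(
        pos,
        {"aha": levels_a, "pha": levels_p, "icsi": (levels_a + levels_p) / 2},
    )
    regions = detect_candidate_regions(mat)
    assert len(regions) == 2
    assert regions.iloc[0]["n_cpgs"] == 3 and regions.iloc[0]["sign"] == 1
    assert regions.iloc[1]["n_cpgs"] == 2 and regions.iloc[1]["sign"] == -1

    uniform = make_meth_matrix(
        pos,
        {"aha": [0.1] * 5, "pha": [0.5] * 5, "icsi": [0.3] * 5},
    )
    one = detect_candidate_regions(uniform)
    assert len(one) == 1 and one.iloc[0]["n_cpgs"] == 5
    assert one.iloc[0]["start"] == 100 and one.iloc[0]["end"] == 321


def test_candidate_regions_match_brute_force_scan():
    """Run-length oracle on a simulated chromosome."""
    cfg = SimConfig(seed=17, n_cpgs=1000, n_planted_dmrs=5,
                    genome=(("chr1", 2_000_000),))
    matrix, _ = simulate_methylomes(cfg)
    matrix = filter_cpgs(matrix)
    regions = detect_candidate_regions(matrix, min_diff=0.1, max_gap_bp=1000)

    lev_a = matrix.pooled_level("aha")
    lev_p = matrix.pooled_level("pha")
    diff = lev_p - lev_a
    valid = np.isfinite(diff) & (np.abs(diff) >= 0.1)
    expected = []
    current = None
    for i in range(matrix.n_cpgs):
        if not valid[i]:
            continue
        s = np.sign(diff[i])
        if (
            current is not None
            and s == current["sign"]
            and matrix.pos[i] - current["last_pos"] <= 1000
        ):
            current["last_pos"] = matrix.pos[i]
            current["n_q"] += 1
        else:
            if current:
                expected.append(current)
            current = {"sign": s, "first": matrix.pos[i], "last_pos": matrix.pos[i], "n_q": 1}
    if current:
        expected.append(current)
    assert len(regions) == len(expected)
    assert list(regions["start"]) == [e["first"] for e in expected]


def test_identical_samples_give_zero_stat_p_one():
    pos = [100, 140, 180, 220, 260]
    mat = make_meth_matrix(pos, {g: [0.3] * 5 for g in ("aha", "pha", "icsi")})
    regions = pd.DataFrame(
        [{"chrom": "chr1", "start": 100, "end": 261, "i0": 0, "i1": 5,
          "n_cpgs": 5, "sign": 1}]
    )
    out = score_and_test_regions(regions, mat)
    assert out.iloc[0]["stat"] == pytest.approx(0.0)
    assert out.iloc[0]["p"] == pytest.approx(1.0)


def test_planted_dmr_power_at_depth_20():
    """A 60-pp DMR at depth 20 should reach FDR 0.1 nearly always."""
    hits = 0
    total = 0
    for seed in range(10):
        cfg = SimConfig(seed=900 + seed, dmr_meth_diff=(0.6, 0.6), n_cpgs=8000,
                        n_planted_dmrs=15)
        matrix, truth = simulate_methylomes(cfg)
        dmrs = call_dmrs(matrix, classify_origin=False)
        rec = recover_known_regions(dmrs, truth.dmr_intervals)
        hits += int(rec["recovered"].sum())
        total += len(rec)
    assert hits / total >= 0.9


def _manual_region_matrix(aha, pha, icsi, n_cpgs=8, spacing=40, depth=25):
    pos = np.arange(100, 100 + n_cpgs * spacing, spacing)
    return make_meth_matrix(
        pos,
        {"aha": [aha] * n_cpgs, "pha": [pha] * n_cpgs, "icsi": [icsi] * n_cpgs},
        depth=depth,
    )


def _tested_region(mat):
    regions = detect_candidate_regions(mat)
    tested = score_and_test_regions(regions, mat)
    tested["padj"] = 0.01  # isolate the non-statistical filters
    return tested


def test_filter_cascade_retains_clear_paternal_dmr():
    mat = _manual_region_matrix(0.80, 0.10, 0.50)
    dmrs = filter_dmrs(_tested_region(mat), mat)
    assert len(dmrs) == 1
    assert dmrs.iloc[0]["parent"] == "paternal"


def test_filter_cascade_requires_icsi_intermediate():
    mat = _manual_region_matrix(0.80, 0.10, 0.90)  # ICSI above both
    assert len(filter_dmrs(_tested_region(mat), mat)) == 0


def test_filter_cascade_minimum_length_coverage_difference():
    # 2 CpGs spanning 41 bp -> fails the 100 bp minimum
    short = _manual_region_matrix(0.8, 0.1, 0.5, n_cpgs=2)
    assert len(filter_dmrs(_tested_region(short), short)) == 0
    # depth 2 x 6 samples x 8 CpGs = 96 reads -> fails 100-read coverage
    thin = _manual_region_matrix(0.8, 0.0, 0.5, depth=2)
    tested = _tested_region(thin)
    if len(tested):
        assert len(filter_dmrs(tested, thin)) == 0
    # 25 pp difference -> fails the 30 pp rule
    weak = _manual_region_matrix(0.50, 0.25, 0.375)
    assert len(filter_dmrs(_tested_region(weak), weak)) == 0


def test_dmr_count_monotone_in_thresholds():
    cfg = SimConfig(seed=31, n_cpgs=8000, n_planted_dmrs=20)
    matrix, _ = simulate_methylomes(cfg)
    base = call_dmrs(matrix, classify_origin=False)
    stricter = [
        call_dmrs(matrix, classify_origin=False, min_diff=0.2),
        call_dmrs(matrix, classify_origin=False, min_len=300),
        call_dmrs(matrix, classify_origin=False, min_cov=400),
        call_dmrs(matrix, classify_origin=False, min_diff_pp=50.0),
    ]
    for s in stricter:
        assert len(s) <= len(base)


def test_origin_class_rules():
    dmrs = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 0, "end": 200, "parent": "maternal"},
            {"chrom": "chr1", "start": 1000, "end": 1200, "parent": "maternal"},
            {"chrom": "chr1", "start": 2000, "end": 2200, "parent": "maternal"},
            {"chrom": "chr1", "start": 3000, "end": 3200, "parent": "maternal"},
            {"chrom": "chr1", "start": 4000, "end": 4200, "parent": "paternal"},
            {"chrom": "chr1", "start": 9000, "end": 9200, "parent": "maternal"},
        ]
    )
    oo = {0: 0.9, 1000: 0.9, 2000: 0.05, 3000: 0.6, 4000: 0.05}
    sp = {0: 0.05, 1000: 0.9, 2000: 0.05, 3000: 0.3, 4000: 0.9}
    pos = np.array(sorted(oo))
    gam = make_meth_matrix(
        pos,
        {"oocyte": [oo[p] for p in pos], "sperm": [sp[p] for p in pos]},
        depth=30,
        groups=["oocyte", "sperm"],
    )
    out = classify_dmr_origin(dmrs, gam)
    assert list(out["origin_class"]) == [
        "C2_oocyte_specific",
        "C4_preimplantation_established",
        "C1_gamete_unmethylated",
        "C3_oocyte_biased",
        "C5_sperm_methylated",
        "unassigned",  # no gamete coverage over 9000-9200
    ]


def test_recovery_bookkeeping_matches_all_pairs_scan():
    rng = np.random.default_rng(3)
    dmrs = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], 200),
            "start": rng.integers(0, 1_000_000, 200),
            "parent": rng.choice(["maternal", "paternal"], 200),
        }
    )
    dmrs["end"] = dmrs["start"] + rng.integers(100, 500, 200)
    ref = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], 100),
            "start": rng.integers(0, 1_000_000, 100),
            "parent": rng.choice(["maternal", "paternal"], 100),
        }
    )
    ref["end"] = ref["start"] + rng.integers(100, 500, 100)
    ref["dmr_id"] = [f"ref{i}" for i in range(100)]
    out = recover_known_regions(dmrs, ref)
    for i, row in enumerate(ref.itertuples()):
        brute = [
            d for d in dmrs.itertuples()
            if d.chrom == row.chrom and d.start < row.end and d.end > row.start
        ]
        assert out.iloc[i]["recovered"] == (len(brute) > 0)
        assert out.iloc[i]["parent_match"] == any(d.parent == row.parent for d in brute)


def test_label_swap_flips_every_parent_and_stat():
    cfg = SimConfig(seed=55, n_cpgs=6000, n_planted_dmrs=15)
    matrix, _ = simulate_methylomes(cfg)
    swap = {"aha": "pha", "pha": "aha"}
    swapped = CpGMethylationMatrix(
        matrix.chrom.copy(), matrix.pos.copy(), matrix.meth.copy(),
        matrix.total.copy(), list(matrix.samples),
        [swap.get(g, g) for g in matrix.groups],
    )
    a = call_dmrs(matrix, classify_origin=False)
    b = call_dmrs(swapped, classify_origin=False)
    assert len(a) == len(b)
    np.testing.assert_array_equal(a["start"], b["start"])
    np.testing.assert_allclose(a["stat"], -b["stat"], atol=1e-12)
    np.testing.assert_allclose(a["padj"], b["padj"], atol=1e-12)
    flip = {"maternal": "paternal", "paternal": "maternal"}
    assert (a["parent"].map(flip).to_numpy() == b["parent"].to_numpy()).all()
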