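"""Gene-DMR-peak-TAD integration and cluster detection."""

import numpy as np
import pandas as pd
import pytest

from imprintscan.integrate import (
    associate_dmr_gene,
    associate_h3k27me3,
    feature_distribution,
    filter_tads,
    find_clusters,
    tad_cooccurrence_test,
)


def ann_frame(entries):
    return pd.DataFrame(
        [
            {"gene": g, "chrom": c, "strand": "+", "tss": t, "start": t, "end": t + 1000}
            for g, c, t in entries
        ]
    )


def dmr_frame(entries):
    df = pd.DataFrame(entries, columns=["chrom", "start", "end"])
    df["dmr_id"] = [f"d{i}" for i in range(len(df))]
    df["parent"] = "maternal"
    return df


def test_distance_windows():
    ann = ann_frame([("g1", "chr1", 1_000_000), ("g2", "chr1", 1_000_000)])
    dmrs = dmr_frame(
        [("chr1", 1_049_900, 1_050_100),   # centre 50 kb away
         ("chr1", 1_239_900, 1_240_100)]   # centre 240 kb away
    )
    out = associate_dmr_gene(ann, dmrs)
    row = out.iloc[0]
    assert row["nearest_dmr"] == "d0"
    assert row["dmr_distance"] == 50_000
    assert row["within_100kb"] and row["within_250kb"]
    only_far = associate_dmr_gene(ann, dmrs.iloc[[1]])
    assert not only_far.iloc[0]["within_100kb"] and only_far.iloc[0]["within_250kb"]


def test_gene_without_dmr_chromosome_gets_nan():
    ann = ann_frame([("g1", "chr9", 500_000)])
    out = associate_dmr_gene(ann, dmr_frame([("chr1", 0, 200)]))
    assert np.isnan(out.iloc[0]["dmr_distance"])
    assert not out.iloc[0]["within_250kb"]


def test_nearest_dmr_matches_all_pairs_scan():
    rng = np.random.default_rng(11)
    ann = ann_frame(
        [(f"g{i}", rng.choice(["chr1", "chr2"]), int(rng.integers(0, 5_000_000)))
         for i in range(300)]
    )
    dmrs = dmr_frame(
        [
            (rng.choice(["chr1", "chr2"]), s, s + 200)
            for s in rng.integers(0, 5_000_000, 80)
        ]
    )
    out = associate_dmr_gene(ann, dmrs).set_index("gene")
    centres = (dmrs["start"] + dmrs["end"]) // 2
    for g in ann.itertuples():
        same = dmrs["chrom"] == g.chrom
        if not same.any():
            assert np.isnan(out.loc[g.gene, "dmr_distance"])
            continue
        d = np.abs(centres[same] - g.tss)
        assert out.loc[g.gene, "dmr_distance"] == d.min()


def test_k27_status_rules():
    ann = ann_frame([("g1", "chr1", 100_000), ("g2", "chr1", 500_000),
                     ("g3", "chr1", 900_000)])
    peak = lambda s, e: pd.DataFrame([{"chrom": "chr1", "start": s, "end": e}])
    peaks = {
        "ICM_maternal": peak(102_000, 104_000),            # 3 kb from g1 TSS
        "ICM_paternal": pd.DataFrame(columns=["chrom", "start", "end"]),
        "ICM_all": pd.concat([peak(102_000, 104_000), peak(499_000, 501_000)]),
        "oocyte": pd.concat([peak(102_000, 104_000), peak(899_000, 901_000)]),
        "sperm": peak(899_000, 901_000),
    }
    out = associate_h3k27me3(ann, peaks).set_index("gene")
    assert out.loc["g1", "k27_tss_status"] == "maternal"
    assert out.loc["g2", "k27_tss_status"] == "both"    # ICM_all only
    assert out.loc["g3", "k27_tss_status"] == "none"
    assert out.loc["g1", "k27_gamete_status"] == "oocyte_specific"
    assert out.loc["g3", "k27_gamete_status"] == "both_gametes"


def test_missing_peak_sets_warn_and_degrade():
    ann = ann_frame([("g1", "chr1", 100_000)])
    with pytest.warns(UserWarning, match="missing"):
        out = associate_h3k27me3(ann, {})
    assert out.iloc[0]["k27_tss_status"] == "none"


def _tiling_tads(n=20, size=100_000, chrom="chr1", score=0.9):
    return pd.DataFrame(
        [{"chrom": chrom, "start": i * size, "end": (i + 1) * size, "score": score}
         for i in range(n)]
    )


def test_tad_score_filter():
    tads = _tiling_tads(4)
    tads.loc[1, "score"] = 0.3
    assert len(filter_tads(tads)) == 3


def test_tad_observed_zero_when_separated():
    tads = _tiling_tads(10)
    ann = ann_frame([("g1", "chr1", 50_000), ("g2", "chr1", 150_000)])
    dmrs = dmr_frame([("chr1", 900_000, 900_200)])  # distinct TAD
    res = tad_cooccurrence_test(ann, dmrs, tads, n_shifts=200, seed=0)
    assert res["observed"] == 0
    assert res["empirical_p"] == 1.0


def test_tad_p_bounds_and_reproducibility():
    rng = np.random.default_rng(2)
    tads = _tiling_tads(20)
    ann = ann_frame([(f"g{i}", "chr1", int(rng.integers(0, 2_000_000))) for i in range(50)])
    dmrs = dmr_frame([("chr1", s, s + 300) for s in rng.integers(0, 2_000_000, 15)])
    r1 = tad_cooccurrence_test(ann, dmrs, tads, n_shifts=500, seed=7)
    r2 = tad_cooccurrence_test(ann, dmrs, tads, n_shifts=500, seed=7)
    assert r1["empirical_p"] == r2["empirical_p"]
    assert 1 / 501 <= r1["empirical_p"] <= 1.0
    np.testing.assert_array_equal(r1["null_counts"], r2["null_counts"])


def test_circular_shift_preserves_pairwise_distances():
    L = 2_000_000
    rng = np.random.default_rng(0)
    g = rng.integers(0, L, 30)
    d = rng.integers(0, L, 10)
    for off in rng.integers(0, L, 20):
        gs = (g + off) % L
        ds = (d + off) % L
        before = (g[:, None] - d[None, :]) % L
        after = (gs[:, None] - ds[None, :]) % L
        np.testing.assert_array_equal(before, after)


def calls_frame(entries):
    return pd.DataFrame([{"gene": g, "novelty": n} for g, n in entries])


def test_two_novel_genes_within_gap_form_novel_only_cluster():
    ann = ann_frame([("a", "chr1", 100_000), ("b", "chr1", 300_000)])
    calls = calls_frame([("a", "nBsX"), ("b", "nBsX")])
    out = find_clusters(calls, ann)
    assert len(out) == 1
    assert out.iloc[0]["type"] == "novel_only"
    assert out.iloc[0]["genes"] == "a,b"


def test_genes_beyond_gap_do_not_cluster():
    ann = ann_frame([("a", "chr1", 100_000), ("b", "chr1", 360_001)])
    calls = calls_frame([("a", "nBsX"), ("b", "nBsX")])
    assert len(find_clusters(calls, ann)) == 0


def test_single_linkage_chains_three_genes():
    ann = ann_frame(
        [("a", "chr1", 100_000), ("b", "chr1", 300_000), ("c", "chr1", 500_000)]
    )
    calls = calls_frame([("a", "nBiX"), ("b", "pubBsX"), ("c", "nBsX")])
    out = find_clusters(calls, ann)
    assert len(out) == 1 and out.iloc[0]["n_genes"] == 3
    assert out.iloc[0]["type"] == "contains_pubBsX"
    # brute-force transitive closure agrees: a-b and b-c within 250 kb
    assert out.iloc[0]["genes"] == "a,b,c"


def test_cluster_membership_invariant_under_input_order():
    ann = ann_frame(
        [("a", "chr1", 100_000), ("b", "chr1", 300_000), ("c", "chr2", 100_000),
         ("d", "chr2", 200_000)]
    )
    calls = calls_frame(
        [("a", "nBsX"), ("b", "published_unconfirmed"), ("c", "nBiX"), ("d", "nBsX")]
    )
    out1 = find_clusters(calls, ann)
    out2 = find_clusters(calls.iloc[::-1].reset_index(drop=True), ann)
    assert list(out1["genes"]) == list(out2["genes"])
    assert out1.iloc[0]["type"] == "published_plus_novel"
    # shrinking the gap can only reduce the number of clusters
    fewer = find_clusters(calls, ann, max_gap=50_000)
    assert len(fewer) <= len(out1)


def test_feature_overlap_fractions_and_oracle():
    features = {
        "gene_body": pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 1_000_000}]
        ),
        "promoter": pd.DataFrame(
            [{"chrom": "chr1", "start": 500_000, "end": 501_000}]
        ),
    }
    dmrs = dmr_frame([("chr1", 10_000, 10_300), ("chr1", 500_500, 500_700)])
    universe = dmr_frame(
        [("chr1", s, s + 300) for s in range(0, 900_000, 10_000)]
    )
    out = feature_distribution(dmrs, features, universe, n_random=50, seed=0)
    row = out.set_index("feature")
    assert row.loc["gene_body", "dmr_fraction"] == 1.0
    assert row.loc["promoter", "dmr_fraction"] == 0.5
    # brute-force oracle on the universe fractions
    bf = np.mean(
        [(s < 501_000) and (s + 300 > 500_000) for s in range(0, 900_000, 10_000)]
    )
    assert abs(row.loc["promoter", "background_mean"] - bf) < 0.1


def test_feature_distribution_requires_big_enough_universe():
    dmrs = dmr_frame([("chr1", 0, 100), ("chr1", 200, 300)])
    with pytest.raises(ValueError, match="universe"):
        feature_distribution(dmrs, {}, dmrs.iloc[[0]], n_random=5)
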