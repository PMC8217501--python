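# Methods

## Allelic count model

Allele-resolved expression is modelled conditionally on the per-gene,
per-sample total of SNP-spanning reads t: the maternal count m follows a
beta-binomial with mean fraction p and overdispersion ρ ∈ [0, 1), so
Var[m] = t·p(1−p)(1+(t−1)ρ) and ρ = 0 recovers the binomial. Conditioning
on totals removes library-size effects by construction, which is why the
pipeline applies no size-factor normalisation to allele columns: the
allelic ratio is ancillary to sequencing depth. This replaces a
negative-binomial two-column fit with an equivalent-in-spirit model that
needs no dispersion trend estimation.

**Overdispersion estimation.** Per gene, ρ is estimated by the method of
moments from the chi-square mass of per-sample counts around the pooled
fraction; estimating the fraction from the same counts costs one degree of
freedom and shrinks the expected excess (E[χ²] = (n−1) + ρ[Σ(t−1) −
Σt(t−1)/T]), which the estimator corrects for. With eight samples the
per-gene estimate is noisy and right-skewed, so each gene's value is shrunk
(weight 0.3 by default) toward the *pooled* across-gene moment estimate —
pooling the excess chi-square mass over genes before dividing. The pooled
target was chosen over the across-gene median because the median of a
right-skewed estimator sits below the true value and inflates the score
statistic; with the pooled target the null p-value distribution is uniform
(checked by KS in the test suite at the study's noise level, ρ = 0.05,
200 reads, 2,000 genes).

**Bias test.** Score test of H₀: p = ½,
z = (Σm − ½Σt)/√(Σ t·¼·(1+(t−1)ρ)), two-sided normal p-value, BH-adjusted
across tested genes. Genes with zero SNP coverage are flagged untestable
and excluded from the BH family.

**Equivalence (biallelic) test.** The pooled log₂ allelic ratio
L = log₂((Σm+½)/(Σp+½)) gets a delta-method standard error from the same
beta-binomial variance, and a TOST against ±1: p_equiv is the larger of the
two one-sided p-values, BH-adjusted. At a true |log₂FC| exactly on the
margin the rejection rate is bounded by the level (measured ≈ 0 after BH,
because nearly all p-values in the family are then uniform); a balanced
gene with 500 reads/sample is declared equivalent with probability > 0.99.
The 0.5 pseudocount keeps estimates finite with zero counts and is used for
every log2FC in the package.

**BsX/BiX cascade.** The rule order is: adjusted bias p ≤ 0.1 →
|log₂FC| > 0.5 → same pooled direction in forward and reverse crosses
(parent-of-origin, not strain) → ≥ 20 SNP reads in each cross → BsX;
additionally ≥ 70:30 toward the called parent in ≥ 60% of each cross's
samples → BiX. Per-sample ratios with fewer than 5 SNP reads are excluded
from the 60% denominator (the source protocol states no per-sample minimum;
5 reads is the smallest count for which a 70:30 call is even expressible).
"Consistent across samples" is operationalised as identical sign of the
pooled per-cross log-ratio, which is what the cross-consistency flag in the
original catalogue encodes.

## DMR calling

Input is a CpG × sample matrix of methylated/total counts for two
replicates each of aha (androgenetic), pha (parthenogenetic) and ICSI
(biparental) blastocysts, plus oocyte and sperm tracks. CpGs need ≥ 3 reads
in ≥ 2 samples.

**Candidates.** CpGs whose pooled pha−aha difference reaches 0.1 with
coverage in both uniparental groups are chained while the sign persists and
consecutive qualifying CpGs are ≤ 1 kb apart; an opposite-sign qualifying
CpG breaks the chain, a sub-threshold CpG in between does not (it is
spanned, and contributes to the region statistic). This skip-chaining
matches how smoothing-based callers assemble candidates and keeps one noisy
CpG from splitting a real DMR into fragments that individually fail the
100-bp length filter.

**Region statistic and null.** Per sample, the region methylation level is
arcsine-sqrt transformed (variance ≈ 1/(4·coverage)); the statistic is the
coverage-weighted group difference divided by its sampling standard error
√(1/(4T_pha)+1/(4T_aha)). Standardisation is essential for the pooled
permutation null: with two replicates per group the per-region permutation
distribution is degenerate, so the null pools statistics from all mixed
relabelings of the four uniparental samples (identity and the pure swap
excluded — the swap only negates the statistic) across all candidate
regions, and pooled statistics are only exchangeable across regions when
they share a scale. p = (1+#{|null| ≥ |stat|})/(1+N), BH across regions.

**Filters.** Emitted DMRs satisfy, and are post-hoc re-asserted to satisfy:
adjusted p ≤ 0.1; ICSI strictly between aha and pha; |aha−pha| ≥ 30
percentage points; |β_aha| ≥ 0.25 and |β_pha| ≥ 0.25; total coverage ≥ 100
reads (aha+pha+ICSI replicates by default, configurable); length ≥ 100 bp.

**The β scale.** β_aha and β_pha are defined as *allele-level* effects
inferred from the uniparental-vs-biparental contrast:
β_group = 2·(mean_group − mean_ICSI). A biparental methylome averages the
two parental alleles, so a fully allele-specific mark moves the ICSI
mixture by only half its allelic effect; the factor 2 de-convolves that.
On the raw mixture scale (available as `beta_scale="mixture"`) the
|β| ≥ 0.25 pair would collapse to |aha−pha| ≥ 0.5, making the separate
30-pp filter vacuous — the two printed filters only coexist meaningfully on
the allele-level scale.

**Origin classes.** Deterministic threshold rules on oocyte/sperm region
methylation replace a hierarchical clustering so class recovery is
testable: maternal DMRs — C2 (oocyte ≥ 0.5, sperm ≤ 0.2), C3 (oocyte−sperm
≥ 0.2, sperm > 0.2), C4 (both ≥ 0.5: established during preimplantation by
paternal-allele demethylation), C1 (both ≤ 0.2); paternal — C5
(sperm ≥ 0.5, oocyte ≤ 0.2), C4, C1. Thresholds are parameters.

## Integration

Distances are TSS-to-DMR-centre, matching the convention that defines TAD
co-membership ("centre of DMR and gene TSS in the same TAD"); nearest-edge
is available as a switch. The TAD null applies one uniform circular offset
per chromosome per iteration jointly to all TSSs and DMR centres
(wrap-around at chromosome length), preserving every pairwise gene–DMR
distance; the empirical p uses the +1 correction and therefore never
returns 0. Genes on chromosomes without (score ≥ 0.5) TADs are excluded
from the denominator. Clusters chain eligible gene TSSs (nBiX/nBsX/
published) within 250 kb by single linkage and keep chains of ≥ 2; cluster
types follow the four published groupings, with "published only, no
blastocyst bias" read as *no BsX member*.

## KO dependence

Each regulator's KO is compared only against its own matched WT. Gates, in
order: no global differential expression between WT and KO (Welch t on
log₂ median-of-ratios-normalised totals, FDR 0.1 — expected empty, warns
otherwise); WT parent-of-origin bias (score test, FDR 0.1, within the
BsX ∪ published family); allelic-ratio dependence on genotype (two-sample
beta-binomial likelihood ratio with plug-in ρ, χ²₁ reference, FDR 0.05);
and |log₂FC| strictly smaller in KO than WT. No magnitude threshold beyond
significance is imposed on the reduction. mEed labels are suppressed for
maternally expressed genes (maternal H3K27me3 silences the maternal allele,
so Eed loss can only de-repress paternally expressed imprints); this
implication is asserted on every output. Amplitude comparisons use the
paired Wilcoxon signed-rank within a dataset (exact null for n ≤ 25, normal
approximation with continuity correction beyond) and the rank-sum test
between WT datasets.

## Enrichment

Fisher tests are one-sided (enrichment); fold is the hit-rate ratio
(odds-ratio switchable) and significance requires both 8-fold enrichment
and BH-adjusted p < 0.005, so sidedness never decides a call. Motif
scanning scores every offset and strand with log₂ likelihood ratios against
the background model; score p-values come from the exact distribution of
the score of a random background word, computed by per-position convolution
on a 10⁻³-bit integer grid, and a region hits when any window reaches
p < 10⁻⁴. N bases never match. Gene-set enrichment is the hypergeometric
upper tail with the robustly expressed genes as background, adj. p < 0.05.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study inputs with planted
truth: reciprocal-cross allelic tables (4+4 samples, Poisson totals at 200
SNP reads, beta-binomial allele split, ρ = 0.05 by default — the embryos'
true allelic overdispersion is not published, so ρ is a free parameter);
imprints at a 90:10 ratio flipping with parent-of-origin, strain-skewed
genes at 70:30 flipping with strain; methylomes with a ~25% blastocyst
baseline, two replicates per group at depth 20, planted 100–500 bp DMRs of
30–60 pp with ICSI exactly the uniparental midpoint and CpG-dense (island-
like) interiors, plus gamete tracks consistent with each planted origin
class; TADs tiling the genome with scores; H3K27me3 peak sets where a
configurable fraction of paternally expressed imprints carries a maternal
ICM + oocyte peak near the TSS; and WT/KO tables at depth 500 where
dependent genes revert to 50:50 in their regulator's KO with unchanged
marginal expression.

It deliberately omits: raw reads and alignment artefacts, bisulfite
conversion failure, CpH methylation, single-cell sparsity, sex chromosomes
(an optional chrX exercises the exclusion filter only), *cis*-linkage
between planted imprinted genes and planted DMRs (genes and DMRs are placed
independently, so TAD/distance associations are null in simulation — the
TAD test is validated for calibration, not power), and biological
between-replicate variance beyond the sampling models. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated noise models, not robustness to every artefact of real embryo data.

## Numerical choices and problem sizes

Benchmarks in the test suite and the reproduction script use: 50 simulation
seeds for the allelic classifier (2,000 genes each) and the DMR caller
(20,000 CpGs each), 1,000 genes for the TOST boundary, 200 replicate
datasets × 2,000 shifts for TAD calibration, and 20 seeds for KO recovery
(depth 500) — sizes at which the measured quantities' Monte-Carlo error is
well below the asserted margins. Score discretisation for motif p-values is
10⁻³ bits; beta-binomial MLEs use bounded scalar minimisation on
[10⁻⁶, 1−10⁻⁶]; empirical p-values all use the +1 correction; percentages
round half away from zero at the printed precision. All randomness flows
from explicit integer seeds through numpy Generators; identical
configurations are byte-identical across runs.

## Known limitations

- The bias/equivalence tests rely on normal approximations of the score
  and pooled log-ratio; below ~20 pooled reads they are conservative
  rather than exact.
- The permutation null for DMRs pools across regions; residual
  region-to-region heterogeneity beyond the standardised scale (e.g.
  biological replicate variance) would make the null slightly misspecified.
  With two replicates per group this is the price of having a null at all.
- The KO global-DE gate is a t-test on normalised log counts, adequate for
  the "expected empty" role it plays, not a replacement for a full
  negative-binomial DE analysis.
- Cluster typing depends on the novelty labels of member genes only; it
  does not re-examine the underlying evidence.
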