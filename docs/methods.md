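# Methods

## The inference problem

In a species with differentiated sex chromosomes, males and females of one
population differ systematically in three observable ways: read depth over
X/Z-differentiated regions (the heterogametic sex maps fewer reads), presence
of Y/W-limited sequence (depth zero in the homogametic sex), and genotype
structure (the heterogametic sex uniformly heterozygous at fixed gametolog
differences, driving intersex Fst toward 0.5). When sex chromosomes are young,
poorly differentiated, population-specific, or absent, each signal is weak and
can be mimicked by noise, so the package runs all of them and calibrates each
against simulations with known planted architecture.

## Coverage-differential scan

**Normalization.** Per site, the median raw depth across the individuals of
each sex; each sex's track is divided by that sex's genome-wide median of site
medians. This cancels global sequencing-effort differences between sexes
(scale invariance: multiplying one sex's raw depths by a constant leaves its
normalized track unchanged) while preserving relative regional reductions.
log2 tracks are provided for plotting only; zero coverage maps to NaN rather
than −∞ (no statistic consumes the log values).

**Window statistics.** Windows tile each chromosome (default 10 kb; a shorter
terminal window is kept — downstream statistics are per-site, so no length
correction is needed). Per window: `ratio` = median over sites of
(norm_m + ε)/(norm_f + ε) with ε = 0.01, sites where both norms are zero
excluded; `diff` = median over all sites of norm_m − norm_f. The pseudocount
gives one-sided-zero sites a finite, rank-preserving ratio; `diff` uses raw
norms. The median-of-site-ratios definition is the default; the ratio of
window medians is available (`site_ratio=False`) for sensitivity analysis.

**Outlier windows.** A window is flagged when its ratio lies outside the
central 99% interval (at or beyond the 0.5th/99.5th percentile) of the
genome-wide window-ratio distribution AND |diff| > 0.25 — the difference
floor corresponds to coverage twice as high in one sex at the hemizygosity
expectation. Both tails are flagged because X-like (reduced male) and Z-like
(reduced female) windows are both informative. The percentile comparison is
inclusive: a tied block of extreme ratios sitting exactly on the percentile
still counts as outside, while the diff floor keeps a constant null
distribution at zero flags. The quantile is genome-wide by construction
(per-chromosome quantiles would absorb a chromosome-wide signal).

**Significance.** Only flagged windows are tested (two-sided paired Wilcoxon
signed-rank on per-site (norm_m, norm_f) pairs, zero differences discarded,
α = 0.05). For ≤ 25 nonzero pairs the p-value is exact: the null distribution
of the positive-rank sum is built by dynamic programming over the observed
midranks (doubled to integers), which handles ties correctly where the
classical no-ties tables do not; above 25 pairs a normal approximation with
tie correction is used. Fewer than 6 nonzero pairs: no test, never
significant. A Hodges–Lehmann estimate and 95% CI of the paired location
shift accompany each test; for large windows the Walsh-average order
statistics are located by value-space bisection with an O(n log n) counting
step instead of materializing the ~n²/2 averages. Both the exact p and the
CI were checked against R's `wilcox.test(conf.int = TRUE)` and against
exhaustive sign-pattern enumeration.

**Chromosome enrichment.** Per chromosome, a one-sided Fisher exact test on
[[sig_c, nonsig_c], [sig_rest, nonsig_rest]], Bonferroni-corrected across
chromosomes (the only place multiplicity is corrected — per-window tests are
reported at α as such), plus significant windows per Mb.

## Sex-limited region calling

A region is a maximal run of positions on a per-sex assembly scaffold where
every opposite-sex individual has depth 0. Runs shorter than 500 bp are
discarded; a run in which ≥ 2 assembly-sex individuals are entirely uncovered
is discarded (one all-zero same-sex individual is tolerated as dropout; the
zero test is region-level, since per-position counting would conflate dropout
with absence). Flanks are extended symmetrically to 5 kb total, shifting the
remainder to the other side at scaffold ends, the whole scaffold when shorter.
Counts of scaffolds carrying regions get exact (Garwood) Poisson 95%
confidence intervals — a Poisson model is appropriate because carrying
scaffolds are a rare subset of tens of thousands. Cross-population redundancy
of flank sequences is grouped by exact duplication/containment on either
strand — a deliberately conservative stand-in for assembly-based collapsing,
sufficient to summarize sharing. Marker screening is exact two-strand
substring search reporting every match location.

## K-mer heterogamety detection

Per specimen, every window of length 37 starting with `AG` is counted on the
read and its reverse complement separately; no canonical collapsing, since
the prefix filter deliberately samples 1/16 of k-mer space and canonicalization
would break its semantics. K-mers present in fewer than 5 specimens are
dropped (this removes nearly all sequencing-error k-mers at ≥ 10× depth).
Ordinary least squares of the summed female count on the summed male count
(raw sums; a log option exists) yields externally studentized (leave-one-out)
residuals; |r| ≥ 3 defines outliers. Among outliers: Y if the female sum is
zero and the male sum positive; W mirrored; otherwise X if female/male > 4,
Z if male/female exceeds the Z threshold (default 4; configurable upward —
e.g. 12 — to compensate an unbalanced sex ratio, the remedy used in the
source study for a female-poor sample, rather than per-specimen
normalization). The heterogamety verdict compares per-k-mer coverage (total
count in the carrying sex) of the Y set vs the W set with a two-sided
rank-sum test, exact when the smaller set has ≤ 20 members and no cross-set
ties: XY if Y coverage is significantly higher, ZW if W wins; with one set
empty the verdict follows the nonempty set only if it holds ≥ 20 k-mers.
The regression direction (female on male) is fixed but immaterial under the
symmetric |r| ≥ 3 rule.

## Intersex population genetics

Weir–Cockerham (1984) two-group θ with males and females as the groups; the
per-site components a, b, c follow the published closed forms and the window
estimate is the ratio of sums Σa/Σ(a+b+c). Negative per-site estimates are
reported as-is (not clamped); with identical allele frequencies in both sexes
the a component is ≤ 0 (it retains the negative finite-sample correction even
at s² = 0), so an undifferentiated genome yields window values scattered
around zero. At a fully sex-linked site with equal per-sex n, a = 0.125,
b = −0.125, c = 0.25, hence Fst = 0.5 exactly for any n ≥ 2. π is the
per-site unbiased pairwise-difference form 2·n_A·n_a/(n(n−1)) summed over
sites and divided by the full window length, the convention of windowed-π
tools (invariant sites count as zero difference). Hard variant filters follow
the conventional GATK-style SNP thresholds; a missing annotation never
triggers removal (matching the behavior of the standard filtration tool);
sites with > 20% missing genotypes or more than two alleles are removed, and
downstream statistics use biallelic SNPs only. The genotype-pattern scan
(fraction of individuals matching the XY or ZW expectation at a site) is a
descriptive screen standing in for association-test genotype inspection; it
is not a significance test and no relatedness correction is attempted.

## Synthetic populations

The generator emulates the study design: one population, 6 males + 6 females
(configurable, ≥ 2 per sex), mean depth 20× per individual, a genome of ten
1-Mb chromosomes. Architectures:

- `none` — background SNPs only (Bernoulli per bp at density 0.001; allele
  frequency from a Beta(0.5, 0.5) prior; Hardy–Weinberg genotypes independent
  of sex).
- `xy_region` / `zw_region` — inside a contiguous region (default the middle
  fifth of chromosome 1), sex-linked SNPs at the gametolog divergence rate
  (default 0.01/bp) with every heterogametic individual heterozygous and the
  other sex homozygous reference.
- `y_insertion` / `w_insertion` — extra scaffolds (default one of 2 kb)
  present only in the heterogametic sex's assembly and reads, covered at
  hemizygous (half) depth there and zero in the other sex.
- `polygenic` — several unlinked loci with partial-penetrance sex association.

Depth is Poisson per site per individual. Two tracks are produced: an
"all reads" track (no reduction anywhere — with permissive mapping, reads of
the diverged gametolog still map) and a strict mismatch-free-mapping track in
which, inside a differentiated region, the heterogametic sex's mean is
mean·(1 + (1−d)^L)/2: a Y/W read survives mismatch-free mapping only if its
whole L-bp span carries no divergent site, so at d = 0.01 and L = 100 about
63% of gametolog reads are lost across the *entire* region — this read-span
effect, not the per-divergent-site halving alone, is what makes the signal
visible to window medians. At the divergent sites themselves survival is
zero and the mean is exactly halved. Reads are fixed-length (100 bp),
uniform-start, drawn from the individual's two haplotypes at half depth each
(insertions ride on the Y/W haplotype, which is why insertion scaffolds sit
at half depth in carriers), with independent per-base substitution errors at
0.001. All randomness derives from one seed; per-specimen substreams are
seeded by (seed, specimen index); identical configurations give byte-identical
outputs.

What the generator does **not** emulate: indels and structural variation
beyond the planted features, linkage disequilibrium and recombination maps,
realistic error/quality profiles, GC and mappability bias, relatedness and
population structure. Passing recovery tests therefore demonstrates the
statistical machinery under the stated model, not robustness to artifacts of
real libraries.

## Calibration and recovery checks (problem sizes)

The test suite and `scripts/acceptance.py` size simulations for a desk-scale
run on one CPU:

- Null calibration: 10 seeds at the default 10 × 1 Mb, 6+6, 20× (depth-only;
  ~1000 windows/seed). Expected and observed: ≲ 1.5% flagged windows (in
  practice 0), no Bonferroni-significant chromosome, zero sex-limited
  regions. The k-mer null runs on a 1 × 60 kb read-bearing genome per seed;
  Y+W k-mers stay below 0.1% of the catalog.
- Region recovery: the planted region is 200 kb (20 windows) on a 10 × 4 Mb
  genome, so the planted mass (0.5% of 4000 windows) matches the regime of a
  real genome scan, where a sex-differentiated region is far below the 1%
  total mass that a central-99%-interval construction can flag. Smaller
  genomes with the same region would self-mask the signal inside the
  quantile — a property of the outlier definition itself worth remembering
  when scanning small assemblies.
- Insertion recovery: 2-kb insertion on a 1 × 60 kb read-bearing genome;
  the region caller recovers ≥ 95% of the insertion span and the k-mer
  verdict is XY.

At 20× depth the jack-knifed-residual outlier rule sits near its power
threshold for individual hemizygous k-mers (the expected studentized residual
of a Y-mer scales as √(depth·containment·n_males/8) ≈ 3.1 at 6 males, 20×,
100-bp reads), so roughly a quarter of true insertion k-mers fall below
|r| = 3 even though the verdict (which pools hundreds of them) is stable;
per-k-mer sensitivity grows with depth. This is inherent to the outlier
definition, not an implementation artifact.

## Numerical and degenerate-input policies

- Windows with no usable site get NaN statistics and are never flagged.
- A sex whose genome-wide median depth is zero is an error (the scan is
  meaningless).
- Monomorphic sites: Fst undefined (NaN), components zero; excluded from
  window sums only when fewer than 2 genotyped individuals per sex.
- Exact-test thresholds: signed-rank exact at ≤ 25 pairs; rank-sum exact at
  ≤ 20 in the smaller set without ties; both switch to tie-corrected normal
  approximations beyond.
- Poisson CIs: k = 0 gives a zero lower bound by convention.
- Collinear k-mer regressions yield undefined studentized residuals; these
  are treated as 0 (no outliers), and zero variance in the predictor is an
  error.
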