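# Methods

`poolsweep` re-implements, as a tested library, a pool-seq selection-scan
workflow of the kind used to look for domestication sweeps in orchard versus
wild tree populations (the motivating system is Chinese chestnut, *Castanea
mollissima*): windowed diversity statistics from pooled read counts, a
permutation null for between-group Tajima's D differences, a gene-interval
allele-fixation outlier scan, pooled chloroplast haplotype deconvolution,
and per-gene validation statistics from individually sequenced genomes.
Because no real read data ship with the package, every stage is exercised on
synthetic data with known truth; this note records the models, defaults, and
judgment calls.

## Pooled window statistics

Per site the alternate-allele frequency is estimated as
`p = alt_count / (ref_count + alt_count)` from the group-combined read
counts (a group's pools are summed site-wise before estimation, mirroring
group-level pileups). Site filters follow the pooled-variant bookkeeping of
the motivating design: a *variant site* has depth > 6 and at least one
alternate read; the tally also reports sites at alternate frequency ≥ 0.2
and the mean depth at variant sites. All downstream statistics use a
stricter uniform coverage floor of 8× so that coverage differences between
groups do not masquerade as diversity differences.

Per 10 kb window (trailing partial windows dropped):

* `S` — segregating sites (0 < p < 1 after filters);
* `π = Σ 2·p·(1−p)·n/(n−1)` — the unbiased per-site heterozygosity summed
  over sites (a per-bp variant is also reported; the per-window sum is the
  default);
* Tajima's `D = (π − S/a1) / sqrt(e1·S + e2·S(S−1))`, with the classic
  coefficients `a1 = Σ 1/i`, `a2 = Σ 1/i²`, `b1 = (n+1)/(3(n−1))`,
  `b2 = 2(n²+n+3)/(9n(n−1))`, `c1 = b1 − 1/a1`,
  `c2 = b2 − (n+2)/(a1·n) + a2/a1²`, `e1 = c1/a1`, `e2 = c2/(a1²+a2)`.
  `D` is undefined (missing) when `S = 0`.

The haploid sample size `n` for a pool group is fixed at twice the number of
diploid individuals in the group (configurable). The pooled-sampling
bias-corrected estimators of PoPoolation are deliberately out of scope: the
downstream inference is a permutation test on D *differences*, which is
insensitive to a common monotone distortion of both tracks, so the classic
read-frequency statistic is used and calibration is restored by the
permutation null itself.

## Permutation scan

The observed track is `Δ_i = D_wild,i − D_orchard,i`, so a diversity loss in
the orchard group makes Δ positive; the test is one-sided in that direction
(a two-sided variant is a trivial wrapper). Each permutation independently
reassigns both groups' observed D values to random window positions and
recomputes Δ. Two counting modes exist and are recorded in the output:

* **per-window** (default): `p_i = (1 + #{Δ_perm,i ≥ Δ_i}) / (1 + n_perm)`;
* **pooled-null**: Δ_i is ranked against the shuffled Δ values of all
  windows and permutations combined.

When the joint permutation count `(m!)²` is at most 10,000 the sampled null
is replaced by exact enumeration. The exact computation uses a reduction:
the value a joint permutation places at window *i* is a uniformly random
pair `(a_j, b_k)`, so the exact exceedance probability is the fraction of
the `m²` value pairs with `a_j − b_k ≥ Δ_i`. This equals brute-force
enumeration of all `(m!)²` joint permutations (cross-checked in the tests)
at quadratic cost.

Candidate regions combine two rules: maximal runs of ≥ 2 adjacent windows at
`p ≤ 0.01` (merged into one call), and isolated windows at `p ≤ 0.001`.
A histogram-based local false discovery rate accompanies the p-values:
`π0 = min(1, #{p > 0.5}/(0.5·m))` (the Storey estimator at λ = 0.5) and
`lfdr(p) = π0 / f̂(p)` with `f̂` a fixed 20-bin histogram density, clipped to
[0, 1] and made monotone non-decreasing in p by a cumulative maximum. A
fixed-bin histogram was preferred over spline-smoothed π0(λ) for
reproducibility; at the scan's scale (10³–10⁴ windows) the difference is
immaterial.

**Calibration and conservatism.** On two tracks realized independently from
the same process, the scan is well calibrated (the fraction of windows at
p ≤ 0.01 is ~0.01; verified over fixed seeds in the acceptance suite). When
the two groups additionally share the *same* underlying site frequencies —
the extreme of undiverged populations — the within-window correlation
between the two D tracks shrinks the observed differences relative to the
shuffled null, and the test becomes conservative (roughly half the nominal
rate in our simulations). This is an inherent property of shuffling whole
windows: it protects the false-positive rate and costs some power, and is
worth knowing when interpreting genome-wide counts of significant windows.

## Fixation outlier scan

Per gene, the major-allele frequency `max(p, 1−p)` is averaged over the
gene's SNPs (genes with zero SNPs, or without a protein-database annotation,
are excluded). Genes are then grouped in genome order into non-overlapping
intervals of 10 (trailing remainders dropped and logged; a sliding variant
exists behind a flag). Per interval, `delta` is the between-group difference
of the interval-averaged statistic; an interval is flagged when `delta`
exceeds the genome-wide mean of delta by more than `k` population standard
deviations. Defaults: `k = 3` for the orchard-vs-wild (domestication)
contrast and `k = 2` for regional (north-vs-south) contrasts; both presets
are exposed because descriptions of such cutoffs vary, and the stricter
value is the domestication default. With thousands of intervals the
population-vs-sample SD distinction is negligible; population SD is used.

## Chloroplast haplotype deconvolution

The chloroplast is effectively haploid and maternally inherited, so a
haplotype carried by a fraction *f* of the copies in a pool leaves its
private SNPs at alternate frequency ≈ *f*. SNPs are tallied into
allele-frequency bins of width 0.10 spanning (0.05, 1.05) — lower edge
inclusive, top bin closed at 1.0 — matching pools of ~10 trees, whose
frequency resolution is 1/10. A bin is called a haplotype peak when it holds
at least 30 SNPs (configurable; the value is a judgment call, chosen well
below the ~75-SNP divergence of the least-diverged haplotype we expect to
resolve and well above the noise floor of a noise-free pool) and strictly
exceeds both neighbors; the 1.0 bin is always reported when supported, since
a fixed haplotype has no neighbor structure. Peaks are matched across pools
by the Jaccard similarity of their member-SNP sets (same haplotype at
≥ 0.5), and haplotype groups are connected components of the match graph.
Known limitation: SNPs shared between co-occurring haplotypes land in the
bin of their summed frequency, inflating intermediate bins; no deconvolution
of shared sites is attempted, and sub-threshold "shoulder" evidence is only
reported in report-all mode (`min_snps=0`).

## Validation statistics from individual genomes

For an independently sequenced panel, per gene and group: `π` per bp
(`2p̂q̂·2N/(2N−1)` summed over sites, divided by the gene interval length, so
monomorphic positions count in the denominator); Tajima's D with constants
taken at the median called-chromosome count across the gene's sites (robust
to missingness); mean heterozygosity averaged per individual (the per-site
average is available too); the two-population Weir & Cockerham (1984) F_ST
as a ratio of summed per-site variance components a, b, c (monomorphic
sites skipped, negative estimates reported raw, matching VCFtools
conventions); and the π ratio between a wild relative and the domesticated
group (infinite when the denominator is 0, flagged rather than raised).
A candidate gene is "supported" when D < 0 and both π/bp and heterozygosity
fall below their genome-wide lower quartiles (thresholds configurable).

## Synthetic data generator

The generator is a coalescent-free statistical stand-in, sufficient to
calibrate the statistics, which respond only to the site-frequency spectrum:

* SNP sites are placed uniformly at an expected density of 0.005/bp
  (1 SNP per 200 bp — diffuse enough that 10 kb windows hold ~50 SNPs,
  comparable to a diverse outcrossing tree after coverage filters);
* each site's ancestral alternate frequency is Beta(0.8, 0.8) — a mildly
  U-shaped spectrum, shared by all groups outside sweeps;
* a sweep interval moves the target group's frequency toward the nearer
  boundary by `fixation_shift` (`p' = p(1−s)` below 0.5, symmetric above)
  and then compresses heterozygosity *exactly* by `diversity_reduction`:
  `p''` solves `2p''(1−p'') = (1−d)·2p'(1−p')` on the same side of 0.5, so
  expected π in a swept window is exactly monotone in `d`;
* pooled sequencing draws `2·n_individuals` chromosomes binomially from the
  group frequency, a Poisson read depth per site, and binomial reads from
  the realized pool frequency with symmetric per-read error 0.001;
* individual genotypes are Hardy–Weinberg draws; chloroplast pools assign
  haplotype copies by largest-remainder rounding of `frequency·n_copies`,
  reproducing grid frequencies exactly in noise-free pools.

The default pool design is the ten-pool orchard/wild structure of the
motivating study (9–13 diploid trees per pool at 4.5–15× expected depth,
orchard and wild-north/wild-south groups). Sweep strength and group
divergence are free parameters with no published values; the defaults
(`diversity_reduction = 0.9`, `fixation_shift = 0`) describe a strong,
nearly complete sweep. The generator has no linkage disequilibrium,
recombination, demography, or indels, and simulates no read-level base
qualities — so passing tests demonstrate the statistical machinery on
spectrum-level signal, not robustness to LD-induced autocorrelation or
alignment artifacts in real data.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; reports are 1-based
  inclusive with explicit headers. Ref/alt orientation follows the input
  file's reference allele; biallelic collapse of sync records keeps the two
  highest summed-count bases (ties broken A<C<G<T).
* Exceedance comparisons in the permutation test use a 1e-12 tolerance so
  exact ties survive floating-point subtraction; with the +1 correction,
  Monte-Carlo p-values are never 0.
* `D` at `S = 1` degenerates to a `sqrt(e1)` denominator and is reported
  as-is; windows with `S = 0` report missing `D` and are excluded from the
  difference track and from shuffling.
* All randomness flows through explicit seeds; per-pool substreams are
  derived from the master seed and the pool id, so adding a pool does not
  perturb the others.

## Problem sizes used in the shipped checks

The acceptance suite runs the calibration study at 2,000 windows (two 10 Mb
linkage groups) with single pools of 10 diploids at 12× and 1,000
permutations over 5 seeds, and the sweep-recovery study at 20 Mb with five
5-window sweeps under the full ten-pool default design over 20 seeds. These
sizes give binomial standard errors small enough to resolve the stated
acceptance bands while keeping the full suite fast.
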