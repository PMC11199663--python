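# Methods

This note documents the models, numerical choices, and simulator assumptions
behind `clonotrace`, in the order data flows through the package.

## Barcode layout and metadata codebook

A library barcode is the concatenation of a randomized region (default 15 nt;
4^15 ≈ 1.07 × 10⁹ sequences) and a block of fixed metadata positions (default
10 nt). The metadata code is a fixed-width positional base-4 code over the
ordered alphabet ACGT: year offset from a base year (2 nt), CLD campaign
number within the year (3 nt), host cell line id (2 nt) and molecule id
(3 nt), most significant digit first. The layout is deliberately a config
object (`Codebook`, JSON-serializable) because any site will want its own
field widths; the only contract is that encode/decode are mutually inverse
over the full tag space and that capacity violations fail loudly, naming the
field. The all-A code is the codebook origin by construction.

Library QC reports abundance-weighted per-position nucleotide frequencies
(rows sum to 1) plus the coefficient of variation and Gini coefficient of
abundances. An evenly synthesized library sits near 0.25 per base with
CV ≲ 0.3.

## Read processing

Amplicons place the barcode between two known flanks (three built-in flank
pairs, one per amplicon design, under `FLANKS["M1"|"M2"|"M3"]`). Processing is
merge-then-extract:

- **Adapter trimming** removes the longest 3' suffix of a mate that equals a
  prefix of the adapter, minimum overlap 3 nt, exact match.
- **Merging** scans all overlap lengths ≥ 10 nt between the forward mate and
  the reverse-complemented reverse mate, keeps the overlap with the most
  matching bases (ties to the longer overlap) if its mismatch fraction is
  ≤ 0.25, and resolves mismatches toward the higher-quality base. Unmerged
  pairs are dropped and counted, not guessed at.
- **Extraction** finds the left flank, then the first right flank after it,
  exact matching by default (`max_flank_mismatches` is exposed but 0 unless
  asked for). If the left flank is absent in forward orientation, the
  reverse complement is searched; if both orientations match, forward wins.
  More than one left-flank hit in an orientation is rejected as ambiguous.
  The insert is kept only when its length equals the expected 15 — indels and
  truncations are discarded rather than repaired.

Every rejection carries a reason (unmerged, flank_not_found, wrong_length,
ambiguous_multiple_hits) and the identity
`total_reads_in = reads_extracted + Σ rejections` is an enforced invariant.

## Genuine-barcode calling

Sequencing errors scatter each true barcode's reads onto a halo of
near-identical sequences, so raw distinct-barcode counts overstate diversity.

**Clustering.** Barcodes are processed smallest count first; each is absorbed
into the highest-count surviving barcode within Levenshtein distance 1 whose
current count is at least 5× its own (ties broken by lexicographically
smallest sequence), and absorbed counts accumulate in the parent. Total count
is conserved and clustering is idempotent. Chains are allowed: a distance-2
straggler adjacent to an already-large distance-1 neighbor merges through it.
Neighbor search uses a deletion-fingerprint index (each sequence keyed by
itself and its single-deletion variants) with candidate verification by exact
edit distance, so 10⁵-barcode tables cluster in seconds; the behavioral
contract — equality with brute-force all-pairs greedy clustering — is pinned
by tests on tables up to 2,000 barcodes.

**Knee point.** The clustered counts are rank-sorted and mapped to
(log10 rank, log10 count). The knee is the point of maximum perpendicular
distance from the chord joining the first and last points. The threshold
depends on which side of the chord that point falls:

- *above* the chord — the knee is the last point of the genuine bulge, and
  the threshold is the count at the next rank;
- *below* the chord — the knee is the first point of the error tail, and the
  threshold is the count at the knee itself.

Genuine barcodes are those with count **strictly greater** than the
threshold; with this convention both cases keep exactly the barcodes left of
the transition. Both geometries occur in practice: a defined pool of equal
clones bulges above the chord, while a heavily skewed mixture (one dominant
clone, then noise) puts the extremum in the tail. A minimum-curvature guard
declares the knee degenerate when no point deviates more than 0.1 decades
from the chord (e.g. an error-free table of equal clones, or a perfect
power-law) and keeps every barcode, with the degeneracy flagged. Tables with
fewer than three barcodes are likewise kept whole. The knee is
scale-invariant: multiplying all counts by c multiplies the threshold by c
and keeps the knee rank.

Cross-contamination checks compare the number of genuine barcodes against an
expected clone count and report each genuine barcode's fraction of clustered
reads, so a 1:100 contaminant surfaces at ~0.01.

## Diversity

- **Chao1**: bias-corrected form `S_obs + f1(f1−1)/(2(f2+1))` by default
  (defined at f2 = 0); the classic `S_obs + f1²/(2 f2)` behind a flag.
  Chao1 belongs on *read-count* abundance vectors from sequencing samples;
  applied to a vector that is nearly all singletons (e.g. raw cell counts
  right after founding) it extrapolates wildly, which is expected behavior,
  not a defect.
- **Resampled richness** draws reads without replacement (multivariate
  hypergeometric) at each requested depth and reports mean ± SD of observed
  and Chao1 richness over replicates, seeded.
- **Collision probability** follows the abundance-weighted
  sample-without-replacement procedure: sample n barcodes proportional to
  abundance, let p be the fraction of sampled items whose barcode occurs
  exactly once in the sample; collision = 1 − p, averaged over replicates.
  On a uniform pool of D ≫ n barcodes this tracks the closed form
  `1 − (1 − 1/D)^(n−1)`.
- **Trajectories** run the knee-filtered caller at every timepoint and report
  genuine counts, retention relative to the first timepoint, and the
  dominant clone's read fraction.
- **RMCE efficiency** is simply genuine clones / transfected cells.

## Probability of clonality

The model treats a grown limited-dilution well as non-clonal only when at
least two of its k seeded cells are the same clone *and* the well still
produced a single outgrowing colony.

- Occupancy: `P_λ(k) = λ^k e^{−λ}/k!`.
- Collision: every cell is assigned the highest normalized clone frequency
  P0 (worst case), giving `P(≥2 identical | k) = 1 − (1 − P0)^k`. The
  product has k factors by default (`convention="as_printed"`, each of the k
  cells contributing a worst-case comparison); `convention="k_minus_1"`
  provides the birthday-style k−1-factor variant for sensitivity analysis.
  (With k factors even a one-cell well has nominal collision probability P0;
  at λ = 0.6 and P0 ≈ 0.03 the difference between conventions is ~0.1
  percentage points of PoC.)
- Outgrowth: `G_k = a` for k = 1, else `k·a·(1−a)^(k−1)` — the probability
  that exactly one of k cells recovers. An alternative reading, requiring at
  least two survivors, would be `1−(1−a)^k − k·a·(1−a)^(k−1)`; the
  single-survivor form is the default, and the simulator's well model
  realizes the same structure so model and simulation stay consistent (a
  `both_grow` flag exists for sensitivity checks).
- Recovery rate: a is the root of
  `N · Σ_{k=1}^{100} P_μ(k)(1−(1−a)^k) = W` found by bisection (brentq) on
  (0, 1) to 1e-10. The truncated sum telescopes via the Poisson generating
  function to `N(1 − e^{−μa})`, so the root must agree with the closed form
  `a = −ln(1 − W/N)/μ` to within truncation error; tests enforce < 1e-10
  agreement across a (μ, W/N) grid. Infeasible plates
  (W ≥ N(1 − e^{−μ})) raise; W = 0 returns the boundary a = 0 with a
  warning. Note the plate equation counts a well as grown when *at least
  one* cell recovers, so parameter-recovery simulations must use that
  convention; the single-survivor G_k applies only inside the collision sum.
- `PoC = 1 − Σ_{k=2}^{k_max} P_λ(k)·(1−(1−P0)^k)·G_k`, k_max = 10 by default
  (occupancies beyond 10 cells/well are negligible at λ ≤ 1; raising k_max
  to 40 changes the sum by < 1e-9).

PoC is monotone non-increasing in P0 and in λ everywhere. In a it is
monotone only while a is below the mixture-weighted peak of G_k (≈ 0.45 at
λ = 0.6): because G_k peaks at a = 1/k, very high recovery rates *reduce*
the modeled collision term again (two survivors no longer count as "one
colony grew"). This is a property of the model itself, not of the
implementation.

## Screening

Clones sharing a barcode ("siblings", ≥ 3 occurrences by default) descend
from one integration event; cohort-unique barcodes are "relatives".
Intermediate multiplicities belong to neither set. The variance comparison
builds |Δ| over all within-sibling-group pairs (pooled across groups) versus
all relative pairs and applies the two-sided Wilcoxon rank-sum test (exact
for small untied samples, otherwise normal approximation with tie and
continuity correction, via `scipy.stats.mannwhitneyu`), with
Benjamini–Hochberg FDR across phenotypes (`statsmodels`). Pairs sharing a
clone are not independent, so the test is anticonservative under the null —
simulations show ~20% rejection at nominal α = 0.05. The procedure is
reproduced as practiced rather than corrected; interpret p-values
comparatively, not as calibrated error rates.

Arm design: the enrichment arm takes `arm_size` clones with pairwise-distinct
barcodes (random lineage, random member); the depletion arm takes `arm_size`
clones from exactly `n_lineages_depletion` barcodes, largest lineages first,
each represented at least once. Max-titer curves sample n titers without
replacement per depth (default 3 replicates, seeded) and report mean ± SD of
the subset maximum; the mean is non-decreasing in depth and the SD vanishes
at full depth.

## Simulator

The generator emulates the CLD process end to end so every stage has truth to
compare against. Defaults are the study conditions where stated, otherwise a
realistic choice made once:

| parameter | default | rationale |
|---|---|---|
| n_transfected | 4.5 × 10⁶ | transfection scale |
| rmce_rate | 2.2 × 10⁻³ | pre-selection barcode counts (~10⁴) per transfection |
| selection_survival | 0.29 | post-/pre-selection barcode ratio (~2.9 × 10³ / 10⁴) |
| growth_rate_mean | 0.69 /day | ~1 doubling/day for CHO suspension culture |
| growth_rate_sd | 0.02 /day | clone-intrinsic heterogeneity; yields ~80% variant loss over an 80-day default run, the observed order of magnitude |
| passage_interval | 3.5 days | 3–4-day passage schedule |
| passage_bottleneck | 2 × 10⁵ cells | scaled-down reseeding density |
| error_rate | 10⁻³ /base | Illumina-like substitution rate |

Growth heterogeneity is modeled as clone-intrinsic fixed rates (diversity as
a pre-existing property), not random walks. Passaging grows clones
deterministically between bottlenecks and resamples hypergeometrically at
each passage (multinomially once populations exceed 10⁹, where the two are
indistinguishable). Limited dilution seeds Poisson(λ) cells per well with
abundance-weighted barcodes and realizes per-cell Bernoulli(a) recovery;
wells grow under the single-survivor convention by default. Sequencing
errors are substitutions only — by design, since indels would simply fall
into the length-15 discard bin; reads come either as full 2×150 mates
(context + flanks + barcode template of 180 nt, ~50% reverse-complemented)
or through a fast merged-read path that collapses error-free reads onto
their template and materializes only error-bearing reads, making 10⁶-read
samples take under a second while remaining read-level faithful.
Fixed seeds give byte-identical outputs.

What the simulator does **not** emulate: PCR amplification bias and
chimeras, quality-score structure (qualities are constant), molecule-specific
selection kinetics, mechanistic metabolism or bioreactor behavior, and any
real library's exact abundance skew. Consequently, passing tests demonstrate
the pipeline's correctness and sensitivity under controlled error and
abundance models, not performance guarantees on arbitrary real runs —
real-data figures that depend on unreleased sequencing or bioreactor data
(exact loss percentages, specific p-values) are reproduced qualitatively
only.

## Problem sizes used in checks

End-to-end sensitivity checks use two-clone mixtures at 1:10–1:1000 with 10⁶
merged reads and 20 seeded replicates per ratio; defined-pool checks use 3,
5, and 17 equal clones at 300× coverage per clone, 20 replicates; recovery-
rate parameter recovery uses 10⁵ simulated wells over 20 seeds. Collision
closed-form checks run on scaled-down uniform pools (e.g. 2 × 10⁵ barcodes,
10³ sampled cells — the same n/D regime as labeling 10⁵ cells from a
> 2 × 10⁷ library, where collision stays below ~0.5%).

## Known limitations

- The knee-point rule is geometric and parameter-free but has one constant
  (0.1-decade minimum curvature); curves hovering near that deviation may
  flip between "knee" and "degenerate, keep all".
- The clustering policy is greedy; pathological count configurations could
  split/merge differently than a global optimizer, though equality with
  brute-force greedy is guaranteed.
- With exact flank matching, every substitution inside a flank costs the
  read; at 0.1%/base this loses ~3% of reads, which the rejection report
  makes visible.
- The PoC model defaults to the k-factor collision product and the
  single-survivor outgrowth term; both conventions are switchable but the
  defaults follow the source formulas.
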