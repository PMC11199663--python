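# clonotrace

Clonal diversity monitoring and control for barcoded, targeted-integration
cell line development (CLD).

When CHO producer cells are built by recombinase-mediated cassette exchange
(RMCE) into a genomic landing pad, a randomized 15-nt barcode integrated next
to the cassette labels every founding clone. Amplicon sequencing of that
barcode then answers questions that imaging and plate statistics cannot: how
many independent integration events survived selection, how fast the pool
skews toward dominant clones, whether a "monoclonal" well really holds one
clone, and which picked clones share a lineage. `clonotrace` implements that
analysis stack end to end, together with a simulator that generates every
input it consumes, so the whole pipeline is testable without sequencing data.

## What it computes

- **Barcode design** (`clonotrace.design`) — a barcode layout of a randomized
  N15 region plus 10 fixed positions that encode cell line metadata (year,
  CLD campaign, host, molecule) through a swappable base-4 codebook; library
  QC via per-position nucleotide frequencies and abundance CV/Gini.
- **Read processing** (`clonotrace.reads`) — adapter trimming, best-overlap
  pair merging with quality-weighted consensus, and flank-anchored barcode
  extraction (forward or reverse-complement) with a strict length-15 filter;
  every rejected read is categorized and counted.
- **Genuine-barcode calling** (`clonotrace.calling`) — greedy Levenshtein-1
  error clustering (children absorbed by ≥5× more abundant neighbors)
  followed by an unbiased knee-point threshold on the log10 rank/count curve:
  barcodes strictly above the knee threshold are genuine clones.
- **Diversity** (`clonotrace.diversity`) — Chao1 richness
  `S_obs + f1(f1−1)/(2(f2+1))` with replicate resampling, abundance-weighted
  collision probability (the chance two independently labeled cells share a
  barcode), diversity-loss trajectories, and RMCE efficiency
  (clones / transfected cells).
- **Probability of clonality** (`clonotrace.clonality`) — for limited
  dilution at Poisson seeding mean λ:

  ```
  P(collision) = Σ_{k=2}^{10}  P_λ(k) · (1 − (1 − P0)^k) · G_k ,
  G_k = a (k = 1),   k·a·(1−a)^(k−1) (k > 1),
  N · Σ_{k=1}^{100} P_μ(k) · (1 − (1−a)^k) = W   (solved for a),
  PoC = 1 − P(collision)
  ```

  with `P0` the highest normalized clone frequency at the time of plating
  (worst case), and `a` the single-cell recovery rate from plate statistics
  (N wells plated, W grown).
- **Screening** (`clonotrace.screening`) — sibling (shared barcode) vs
  relative (unique barcode) classification, pairwise |Δphenotype| comparison
  by Wilcoxon rank-sum with Benjamini–Hochberg FDR, diversity
  enrichment/depletion arm design, and the max-titer-versus-screening-depth
  subsampling curve.
- **Simulation** (`clonotrace.simulate`) — library skew, transfection/RMCE
  founding, selection, passaging with bottlenecks, limited dilution under the
  same outgrowth model the PoC uses, variance-components phenotypes, and
  error-bearing amplicon reads (full 2×150 pairs or a fast merged-read path).

## Worked example

Probability of clonality from plate statistics (7767 wells plated, 1552 with
growth, λ = 0.6) and a limited-dilution pool whose dominant clone holds 3%:

```python
import numpy as np
from clonotrace import ClonalityInput, PlateStats, probability_of_clonality

plate = PlateStats(n_wells_plated=7767, n_wells_grown=1552, seeding_mean=0.6)
freqs = np.array([0.03] + [(1 - 0.03) / 193] * 193)
res = probability_of_clonality(ClonalityInput(plate=plate, clone_frequencies=freqs))
print(f"a = {res.recovery_rate:.3f}, PoC = {100 * res.poc:.2f}%")
```

prints

```
a = 0.372, PoC = 99.64%
```

meaning only 37.2% of seeded single cells outgrow into a colony, and the
probability that a grown well descends from a single clone — after accounting
for multi-cell wells, worst-case barcode collisions, and outgrowth — is
99.6%. The `examples/` directory holds one narrative script per capability
(library design, extraction, calling, diversity, PoC, screening), each
printing the numbers it computes and what they mean. A thin CLI mirrors the
library: `clonotrace extract|call|diversity|collision|poc|screen|arms|simulate`.

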