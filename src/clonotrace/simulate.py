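"""Synthetic-data generator for the barcoded cell line development process.

Emulates the workflow end to end: a barcode plasmid library with controllable
abundance skew, the transfection/RMCE founding bottleneck and selection, clone
growth dynamics with passage bottlenecks, Poisson limited dilution with the
single-survivor outgrowth model, variance-components clone phenotypes, and
error-bearing amplicon reads (both full 2x150 read pairs and a fast
count-level path for deep merged-read samples).

Defaults mirror the study conditions: 4.5e6 transfected cells, ~2.2e-3
RMCE founding rate with ~29% selection survival (pre-/post-selection barcode
counts of roughly 10^4 vs 3x10^3), passaging every 3.5 days, 0.1%/base
substitution errors, 15-nt barcodes between known flanks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .design import BarcodeLibrary, BarcodeSpec
from .reads import CountTable, FlankSpec, ReadPair, reverse_complement
from .screening import CloneRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# _ALT[b, j] = the j-th alternative base for base index b
_ALT = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    n_transfected: int = 4_500_000
    rmce_rate: float = 2.2e-3
    selection_survival: float = 0.29
    growth_rate_mean: float = 0.69     # 1/day, ~1 doubling/day
    growth_rate_sd: float = 0.02       # 1/day, clone-intrinsic spread
    passage_interval: float = 3.5      # days
    passage_bottleneck: int = 200_000  # cells kept per passage
    error_rate: float = 1e-3           # substitutions per base
    reads_per_sample: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rmce_rate", "selection_survival"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class SimPool:
    """Simulation state: barcode -> abundance and clone-intrinsic growth rate."""

    abundances: Dict[str, float]
    growth_rates: Dict[str, float]
    time: float = 0.0
    collision_fraction: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be >= 0")

    @property
    def total(self) -> float:
        return float(sum(self.abundances.values()))

    def to_table(self, sample_id: str = "") -> CountTable:
        counts = {b: int(round(v)) for b, v in self.abundances.items() if round(v) >= 1}
        return CountTable(counts=counts, sample_id=sample_id)


def random_barcodes(n: int, length: int, rng: np.random.Generator) -> List[str]:
    """n distinct random sequences of the given length."""
    if n > 4**length:
        raise ValueError(f"cannot draw {n} distinct {length}-mers (capacity {4**length})")
    out: set = set()
    while len(out) < n:
        need = n - len(out)
        arr = _BASES[rng.integers(0, 4, size=(need, length))]
        out.update(a.tobytes().decode() for a in arr)
    return sorted(out)[:n]


def simulate_library(
    spec: BarcodeSpec,
    n_variants: int,
    skew: float = 0.0,
    seed: Optional[int] = None,
    mean_abundance: float = 100.0,
) -> BarcodeLibrary:
    """Library of n_variants distinct random-region sequences.

    ``skew`` is the target coefficient of variation of the abundances; 0
    gives a perfectly even library, otherwise abundances are log-normal with
    sigma = sqrt(ln(1 + skew^2)).
    """
    rng = np.random.default_rng(seed)
    if n_variants > 4**spec.random_length:
        raise ValueError(
            f"n_variants {n_variants} exceeds 4^{spec.random_length} capacity"
        )
    seqs = random_barcodes(n_variants, spec.random_length, rng)
    if skew == 0:
        abund = np.full(n_variants, mean_abundance)
    else:
        sigma = math.sqrt(math.log(1.0 + skew**2))
        abund = rng.lognormal(mean=math.log(mean_abundance) - sigma**2 / 2, sigma=sigma, size=n_variants)
    entries = {s: max(1, int(round(a))) for s, a in zip(seqs, abund)}
    return BarcodeLibrary(entries=entries, spec=spec)


def simulate_pool_founding(
    lib: BarcodeLibrary, cfg: SimConfig, seed: Optional[int] = None
) -> SimPool:
    """Transfection founding + selection: draws founders from the library.

    Founders = Binomial(n_transfected, rmce_rate) abundance-weighted draws
    with replacement (library collisions possible and tracked), thinned by
    selection_survival; each surviving lineage gets a truncated-normal
    growth rate.
    """
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    n_founders = int(rng.binomial(cfg.n_transfected, cfg.rmce_rate))
    if n_founders == 0 or not lib.entries:
        return SimPool(abundances={}, growth_rates={})
    seqs = list(lib.entries)
    weights = np.array([lib.entries[s] for s in seqs], dtype=float)
    weights /= weights.sum()
    draws = rng.choice(len(seqs), size=n_founders, p=weights, replace=True)
    unique, counts = np.unique(draws, return_counts=True)
    collision_fraction = 1.0 - len(unique) / n_founders
    survivors = rng.binomial(counts, cfg.selection_survival)
    abundances: Dict[str, float] = {}
    growth: Dict[str, float] = {}
    for idx, surv in zip(unique, survivors):
        if surv == 0:
            continue
        bc = seqs[idx]
        abundances[bc] = float(surv)
        r = rng.normal(cfg.growth_rate_mean, cfg.growth_rate_sd)
        growth[bc] = max(r, 0.0)
    return SimPool(
        abundances=abundances,
        growth_rates=growth,
        collision_fraction=float(collision_fraction),
    )


def simulate_passaging(
    pool: SimPool,
    days: float,
    cfg: SimConfig,
    timepoints: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
):
    """Grow-and-split culture dynamics with abundance snapshots.

    Between passages each clone grows deterministically as exp(r_i * dt); at
    each passage a multivariate-hypergeometric bottleneck keeps
    ``passage_bottleneck`` cells.  Returns a PoolTimeSeries of snapshots at
    the requested timepoints (default: 0 and the final day).
    """
    from .diversity import PoolTimeSeries  # local import avoids a cycle

    if not pool.abundances:
        raise ValueError("empty pool")
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    if timepoints is None:
        timepoints = [0.0, float(days)]
    timepoints = sorted(float(t) for t in timepoints)

    barcodes = list(pool.abundances)
    abund = np.array([pool.abundances[b] for b in barcodes], dtype=float)
    rates = np.array([pool.growth_rates.get(b, cfg.growth_rate_mean) for b in barcodes])

    snapshots: List[CountTable] = []
    snap_iter = iter(timepoints)
    next_snap = next(snap_iter, None)

    def take_snapshots(t_now: float):
        nonlocal next_snap
        while next_snap is not None and next_snap <= t_now + 1e-9:
            counts = {b: int(round(a)) for b, a in zip(barcodes, abund) if round(a) >= 1}
            snapshots.append(CountTable(counts=counts, sample_id=f"d{next_snap:g}"))
            next_snap = next(snap_iter, None)

    t = 0.0
    take_snapshots(t)
    while t < days - 1e-9:
        dt = min(cfg.passage_interval, days - t)
        abund = abund * np.exp(rates * dt)
        t += dt
        total = abund.sum()
        if total > cfg.passage_bottleneck:
            ints = np.maximum(np.round(abund).astype(np.int64), 0)
            ints[abund > 0] = np.maximum(ints[abund > 0], 1)
            n_keep = int(min(cfg.passage_bottleneck, ints.sum()))
            if ints.sum() < 10**9:
                abund = rng.multivariate_hypergeometric(ints, n_keep).astype(float)
            else:
                # population >> sample: multinomial is an excellent stand-in
                # for the hypergeometric draw and avoids huge-integer limits
                abund = rng.multinomial(n_keep, abund / total).astype(float)
        take_snapshots(t)
    # any snapshot times beyond the simulated horizon get the final state
    take_snapshots(float("inf"))
    return PoolTimeSeries(timepoints=list(timepoints), tables=snapshots)


# ---------------------------------------------------------------------------
# limited dilution


@dataclass
class WellOutcome:
    k: int
    barcodes: Tuple[str, ...]
    grew: bool
    founders: Tuple[str, ...] = ()


def simulate_limited_dilution(
    pool: SimPool,
    lam: float,
    a: float,
    n_wells: int,
    seed: Optional[int] = None,
    both_grow: bool = False,
) -> List[WellOutcome]:
    """Poisson well seeding with per-cell recovery.

    k ~ Poisson(lam) cells per well, barcodes drawn proportional to pool
    abundance; each cell independently recovers with probability a.  Under
    the default single-survivor outgrowth model a well grows iff exactly one
    cell recovers (matching G_k = k a (1-a)^(k-1)); with ``both_grow`` a well
    grows when at least one cell recovers.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if not 0 <= a <= 1:
        raise ValueError("a must be in [0, 1]")
    rng = np.random.default_rng(seed)
    barcodes = list(pool.abundances)
    weights = np.array([pool.abundances[b] for b in barcodes], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("empty pool")
    weights /= weights.sum()
    ks = rng.poisson(lam, size=n_wells)
    wells: List[WellOutcome] = []
    for k in ks:
        if k == 0:
            wells.append(WellOutcome(0, (), False))
            continue
        cells = tuple(barcodes[i] for i in rng.choice(len(barcodes), size=k, p=weights))
        recovered = rng.random(k) < a
        n_rec = int(recovered.sum())
        grew = n_rec >= 1 if both_grow else n_rec == 1
        founders = tuple(b for b, r in zip(cells, recovered) if r) if grew else ()
        wells.append(WellOutcome(int(k), cells, bool(grew), founders))
    return wells


# ---------------------------------------------------------------------------
# amplicon reads

_LEFT_CONTEXT_LEN = 60
_RIGHT_CONTEXT_LEN = 75


def _context(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def amplicon_template(
    barcode: str, flanks: FlankSpec, left_context: str, right_context: str
) -> str:
    return left_context + flanks.left_flank + barcode + flanks.right_flank + right_context


def simulate_read_pairs(
    table: CountTable,
    flanks: FlankSpec,
    cfg: SimConfig,
    n_reads: Optional[int] = None,
    seed: Optional[int] = None,
    read_length: int = 150,
) -> Iterator[ReadPair]:
    """Error-bearing 2x150 read pairs from a barcode abundance table.

    Each read derives from a ~180-nt template (context + flanks + barcode);
    mates are the first/last ``read_length`` bases, overlapping in the
    middle; ~50% of templates are emitted reverse-complemented; per-base
    substitutions at cfg.error_rate.
    """
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    n_reads = n_reads or cfg.reads_per_sample
    barcodes = list(table.counts)
    weights = np.array([table.counts[b] for b in barcodes], dtype=float)
    weights /= weights.sum()
    left_ctx = _context(rng, _LEFT_CONTEXT_LEN)
    right_ctx = _context(rng, _RIGHT_CONTEXT_LEN)
    picks = rng.choice(len(barcodes), size=n_reads, p=weights)
    flips = rng.random(n_reads) < 0.5
    qual = "I" * read_length
    for i, (pick, flip) in enumerate(zip(picks, flips)):
        template = amplicon_template(barcodes[pick], flanks, left_ctx, right_ctx)
        arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
        errs = rng.random(arr.size) < cfg.error_rate
        if errs.any():
            idx = np.where(errs)[0]
            base_idx = np.searchsorted(_BASES, arr[idx])
            arr[idx] = _BASES[_ALT[base_idx, rng.integers(0, 3, size=idx.size)]]
        seq = arr.tobytes().decode()
        if flip:
            seq = reverse_complement(seq)
        fwd = seq[:read_length]
        rev = reverse_complement(seq[-read_length:])
        yield ReadPair(f"sim_{i}", fwd, qual[: len(fwd)], rev, qual[: len(rev)])


def simulate_merged_reads(
    fractions: Dict[str, float],
    n_reads: int,
    flanks: FlankSpec,
    error_rate: float = 1e-3,
    seed: Optional[int] = None,
    rc_fraction: float = 0.5,
) -> Dict[str, int]:
    """Deep merged-amplicon sample as a (sequence -> multiplicity) mapping.

    Equivalent to merging error-bearing pairs whose overlap carries no
    conflicting errors: per-base substitutions are applied across the whole
    template.  Error-free reads collapse onto their template with a single
    large multiplicity, so 10^6-read samples are generated in seconds;
    error-bearing reads are materialized individually.
    """
    rng = np.random.default_rng(seed)
    barcodes = list(fractions)
    weights = np.array([fractions[b] for b in barcodes], dtype=float)
    weights /= weights.sum()
    left_ctx = _context(rng, _LEFT_CONTEXT_LEN)
    right_ctx = _context(rng, _RIGHT_CONTEXT_LEN)
    per_clone = rng.multinomial(n_reads, weights)
    out: Dict[str, int] = {}

    def add(seq: str, mult: int) -> None:
        out[seq] = out.get(seq, 0) + mult

    for bc, n_clone in zip(barcodes, per_clone):
        if n_clone == 0:
            continue
        template = amplicon_template(bc, flanks, left_ctx, right_ctx)
        tmpl_arr = np.frombuffer(template.encode(), dtype=np.uint8)
        L = tmpl_arr.size
        n_err = int(rng.binomial(n_clone, 1.0 - (1.0 - error_rate) ** L))
        n_clean = n_clone - n_err
        if n_clean:
            n_rc = int(rng.binomial(n_clean, rc_fraction))
            if n_clean - n_rc:
                add(template, n_clean - n_rc)
            if n_rc:
                add(reverse_complement(template), n_rc)
        if n_err == 0:
            continue
        # number of substitutions per error-bearing read: Binomial(L, e) truncated at >= 1
        m = rng.binomial(L, error_rate, size=n_err)
        m[m == 0] = 1
        arr = np.tile(tmpl_arr, (n_err, 1))
        singles = np.where(m == 1)[0]
        if singles.size:
            pos = rng.integers(0, L, size=singles.size)
            base_idx = np.searchsorted(_BASES, arr[singles, pos])
            arr[singles, pos] = _BASES[_ALT[base_idx, rng.integers(0, 3, size=singles.size)]]
        for row in np.where(m > 1)[0]:
            pos = rng.choice(L, size=int(m[row]), replace=False)
            base_idx = np.searchsorted(_BASES, arr[row, pos])
            arr[row, pos] = _BASES[_ALT[base_idx, rng.integers(0, 3, size=pos.size)]]
        flips = rng.random(n_err) < rc_fraction
        for row in range(n_err):
            seq = arr[row].tobytes().decode()
            add(reverse_complement(seq) if flips[row] else seq, 1)
    return out


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    clone_barcodes: Sequence[str],
    phenotypes: Optional[Dict[str, Tuple[float, float, float]]] = None,
    seed: Optional[int] = None,
) -> List[CloneRecord]:
    """Variance-components phenotypes for a cohort of clones.

    ``clone_barcodes`` lists one barcode per clone (repeats = sibling
    clones).  Each phenotype is specified as (global_mean, between_sd,
    within_sd): every lineage draws a mean ~ Normal(global, between_sd) and
    every clone draws ~ Normal(lineage mean, within_sd).
    """
    if phenotypes is None:
        phenotypes = {"titer": (2000.0, 400.0, 80.0)}
    rng = np.random.default_rng(seed)
    lineage_means: Dict[str, Dict[str, float]] = {}
    records: List[CloneRecord] = []
    for i, bc in enumerate(clone_barcodes):
        if bc not in lineage_means:
            lineage_means[bc] = {
                name: rng.normal(mean, b_sd)
                for name, (mean, b_sd, _w) in phenotypes.items()
            }
        values = {
            name: float(rng.normal(lineage_means[bc][name], w_sd))
            for name, (_m, _b, w_sd) in phenotypes.items()
        }
        records.append(CloneRecord(clone_id=f"clone_{i:03d}", barcode=bc, phenotypes=values))
    return records
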