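"""Probability-of-clonality model for limited-dilution single cell cloning.

At a Poisson seeding mean λ per well, a grown well may still descend from two
cells of the same clone — an undetectable collision.  The model combines:

* Poisson well occupancy P_λ(k);
* a worst-case barcode-collision term that assigns every cell the highest
  normalized clone frequency P0, giving
  P(at least two identical | k) = 1 - (1 - P0)^k;
* colony-outgrowth probabilities G_k = a (k = 1) or k a (1-a)^(k-1) (k > 1),
  where the single-cell recovery rate a is solved from plate-level growth
  statistics N (wells plated), W (wells grown) and seeding mean μ via
  N * Σ_{k=1}^{100} P_μ(k) (1 - (1-a)^k) = W.

The probability of clonality is 1 minus the sum over k = 2..k_max of the
product of the three factors.  The collision product uses k factors by
default (every cell compared against the worst-case clone); a ``convention``
switch offers the (k-1)-factor birthday-style variant for sensitivity
analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .reads import CountTable


def poisson_pmf(k: int, lam: float) -> float:
    """Exact Poisson mass λ^k e^{-λ} / k!."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    return math.exp(k * math.log(lam) - lam - math.lgamma(k + 1))


@dataclass(frozen=True)
class PlateStats:
    """Plate-level growth statistics of a limited-dilution experiment."""

    n_wells_plated: int
    n_wells_grown: int
    seeding_mean: float
    growth_definition: str = "> 10% confluence on day 18"

    def __post_init__(self) -> None:
        if not 0 <= self.n_wells_grown <= self.n_wells_plated:
            raise ValueError("need 0 <= W <= N")
        if self.seeding_mean <= 0:
            raise ValueError("seeding_mean must be > 0")


class InfeasiblePlateError(ValueError):
    """W exceeds the maximum achievable number of occupied wells."""


def solve_recovery_rate(plate: PlateStats, k_trunc: int = 100) -> float:
    """Single-cell recovery rate a from plate statistics.

    Solves N * Σ_{k=1}^{k_trunc} P_μ(k) * (1 - (1-a)^k) = W for a in (0, 1]
    by bisection (brentq) to absolute tolerance 1e-10.  The truncated sum
    telescopes to N (1 - e^{-μ a}) as k_trunc → ∞, so the root agrees with
    the closed form a = -ln(1 - W/N) / μ up to truncation error.
    """
    N, W, mu = plate.n_wells_plated, plate.n_wells_grown, plate.seeding_mean
    if W == 0:
        warnings.warn("no wells grew: recovery rate at boundary a = 0")
        return 0.0
    occupancy = 1.0 - math.exp(-mu)
    if W >= N * occupancy:
        raise InfeasiblePlateError(
            f"W = {W} >= N (1 - e^-mu) = {N * occupancy:.3f}: growth exceeds occupancy"
        )
    pmf = np.array([poisson_pmf(k, mu) for k in range(1, k_trunc + 1)])
    ks = np.arange(1, k_trunc + 1)

    def objective(a: float) -> float:
        return float(N * np.sum(pmf * (1.0 - (1.0 - a) ** ks)) - W)

    return float(brentq(objective, 1e-12, 1.0 - 1e-15, xtol=1e-10))


def recovery_rate_closed_form(plate: PlateStats) -> float:
    """Closed-form limit -ln(1 - W/N) / μ of the recovery-rate equation."""
    frac = plate.n_wells_grown / plate.n_wells_plated
    if frac >= 1:
        raise InfeasiblePlateError("W must be < N")
    return -math.log(1.0 - frac) / plate.seeding_mean


def growth_probability(k: int, a: float) -> float:
    """G_k: probability a well seeded with k cells shows colony growth.

    a for k = 1, otherwise k a (1-a)^(k-1) — the chance that exactly one of
    the k cells recovers while the others do not.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= a <= 1:
        raise ValueError("a must be in [0, 1]")
    if k == 1:
        return a
    return k * a * (1.0 - a) ** (k - 1)


def p_at_least_two_identical(k: int, p0: float, convention: str = "as_printed") -> float:
    """Worst-case probability that at least two of k cells are the same clone.

    With every cell assigned the highest clone frequency p0, the default
    all-different product has k factors, giving 1 - (1 - p0)^k; the
    "k_minus_1" convention uses the birthday-style k-1 factors.
    """
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must be in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    exponent = k if convention == "as_printed" else k - 1
    if convention not in ("as_printed", "k_minus_1"):
        raise ValueError(f"unknown convention {convention!r}")
    return 1.0 - (1.0 - p0) ** exponent


@dataclass
class ClonalityInput:
    """Plate statistics plus normalized clone frequencies at limited dilution."""

    plate: PlateStats
    clone_frequencies: np.ndarray
    k_max: int = 10
    seeding_lambda: Optional[float] = None  # defaults to plate.seeding_mean

    def __post_init__(self) -> None:
        freqs = np.asarray(self.clone_frequencies, dtype=float)
        if len(freqs) == 0:
            raise ValueError("clone_frequencies must be non-empty")
        if freqs.min() < 0:
            raise ValueError("clone frequencies must be >= 0")
        total = freqs.sum()
        if total <= 0:
            raise ValueError("clone frequencies sum to zero")
        if abs(total - 1.0) > 1e-9:  # raw counts: normalize
            freqs = freqs / total
        self.clone_frequencies = freqs
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.seeding_lambda is None:
            self.seeding_lambda = self.plate.seeding_mean

    @classmethod
    def from_table(cls, plate: PlateStats, table: CountTable, **kw) -> "ClonalityInput":
        return cls(plate=plate, clone_frequencies=np.array(list(table.counts.values()), float), **kw)

    @property
    def p0(self) -> float:
        return float(self.clone_frequencies.max())


@dataclass
class PoCResult:
    recovery_rate: float
    p_collision: float
    poc: float
    per_k_terms: Dict[int, float] = field(default_factory=dict)
    p0: float = 0.0
    convention: str = "as_printed"


def probability_of_clonality(
    inp: ClonalityInput,
    convention: str = "as_printed",
    recovery_rate: Optional[float] = None,
) -> PoCResult:
    """Probability that a grown limited-dilution well is truly clonal.

    p_collision = Σ_{k=2}^{k_max} P_λ(k) * (1 - (1-P0)^k) * G_k with
    P0 = max normalized clone frequency and a from
    :func:`solve_recovery_rate` (unless supplied); PoC = 1 - p_collision.
    """
    a = solve_recovery_rate(inp.plate) if recovery_rate is None else recovery_rate
    lam = float(inp.seeding_lambda)
    p0 = inp.p0
    terms: Dict[int, float] = {}
    for k in range(2, inp.k_max + 1):
        terms[k] = (
            poisson_pmf(k, lam)
            * p_at_least_two_identical(k, p0, convention)
            * growth_probability(k, a)
        )
    p_collision = float(sum(terms.values()))
    return PoCResult(
        recovery_rate=a,
        p_collision=p_collision,
        poc=1.0 - p_collision,
        per_k_terms=terms,
        p0=p0,
        convention=convention,
    )


def estimate_recovery_rate_from_simulation(
    ks: Sequence[int], grew: Sequence[bool], seeding_mean: float
) -> float:
    """Recovery-rate estimate from simulated well outcomes via the plate solver.

    The plate equation treats a well as grown when at least one of its k
    cells recovers (the 1 - (1-a)^k term), so unbiased recovery requires
    wells simulated under that convention.
    """
    ks = np.asarray(ks)
    grew = np.asarray(grew, dtype=bool)
    if len(ks) != len(grew):
        raise ValueError("ks/grew length mismatch")
    plate = PlateStats(
        n_wells_plated=len(ks),
        n_wells_grown=int(grew.sum()),
        seeding_mean=seeding_mean,
    )
    return solve_recovery_rate(plate)
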