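"""Pool clonal diversity: Chao1 richness, resampling, collision probability, dynamics.

Richness of a barcode pool is estimated with the Chao1 capture-recapture
estimator from singleton and doubleton counts, optionally across replicate
resampling at varying depths.  Collision probability — the chance that
independently labeled cells share a barcode by coincidence — is estimated by
abundance-weighted sampling without replacement.  Time-course diagnostics
(retention, dominant-clone fraction) quantify diversity loss during
cultivation, and RMCE efficiency relates surviving clone numbers to the
number of transfected cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calling import ClusteringParams, call_genuine
from .reads import CountTable


@dataclass
class AbundanceVector:
    abundances: np.ndarray
    labels: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=np.int64)
        if self.labels is not None and len(self.labels) != len(self.abundances):
            raise ValueError("labels/abundances length mismatch")
        if len(self.abundances) and self.abundances.min() < 1:
            raise ValueError("abundances must be >= 1")

    @classmethod
    def from_table(cls, table: CountTable) -> "AbundanceVector":
        labels = [s for s, c in table.counts.items() if c > 0]
        return cls(np.array([table.counts[s] for s in labels]), labels)

    @property
    def total(self) -> int:
        return int(self.abundances.sum())


@dataclass
class PoolTimeSeries:
    timepoints: List[float]
    tables: List[CountTable]
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.tables):
            raise ValueError("timepoints/tables length mismatch")
        if not self.timepoints:
            raise ValueError("at least one timepoint required")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")


def chao1(v: AbundanceVector, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singletons (f1) and doubletons (f2).

    Classic form S_obs + f1^2 / (2 f2); the bias-corrected form
    S_obs + f1 (f1 - 1) / (2 (f2 + 1)) stays defined at f2 = 0 and is the
    default.  Always >= observed richness.
    """
    if len(v.abundances) == 0:
        raise ValueError("empty abundance vector")
    s_obs = len(v.abundances)
    f1 = int((v.abundances == 1).sum())
    f2 = int((v.abundances == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    return s_obs + f1 * f1 / (2 * f2)


def resampled_richness(
    v: AbundanceVector,
    depths: Sequence[int],
    replicates: int = 20,
    seed: Optional[int] = None,
    bias_corrected: bool = True,
) -> pd.DataFrame:
    """Observed and Chao1 richness from replicate subsampling at given depths.

    Reads are drawn without replacement (multivariate hypergeometric); the
    returned frame has per-depth mean and SD over replicates.
    """
    rng = np.random.default_rng(seed)
    total = v.total
    rows = []
    for depth in depths:
        depth = int(depth)
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total abundance {total}")
        if depth < 1:
            raise ValueError("depth must be >= 1")
        obs, est = [], []
        for _ in range(replicates):
            draw = rng.multivariate_hypergeometric(v.abundances, depth)
            kept = draw[draw > 0]
            obs.append(len(kept))
            est.append(chao1(AbundanceVector(kept), bias_corrected=bias_corrected))
        rows.append(
            {
                "depth": depth,
                "observed_mean": float(np.mean(obs)),
                "observed_sd": float(np.std(obs, ddof=0)),
                "chao1_mean": float(np.mean(est)),
                "chao1_sd": float(np.std(est, ddof=0)),
            }
        )
    return pd.DataFrame(rows)


def collision_probability(
    v: AbundanceVector,
    n_cells: int,
    replicates: int = 20,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Fraction of sampled cells sharing a barcode by coincidence.

    For each replicate, ``n_cells`` barcodes are sampled without replacement
    with probability proportional to abundance; p is the fraction of sampled
    items whose barcode occurs exactly once in the sample, and the collision
    probability is 1 - p.  Returns (mean, SD) over replicates.
    """
    if n_cells > v.total:
        raise ValueError(f"n_cells {n_cells} exceeds total abundance {v.total}")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(replicates):
        draw = rng.multivariate_hypergeometric(v.abundances, n_cells)
        unique_cells = int(draw[draw == 1].sum())
        vals.append(1.0 - unique_cells / n_cells)
    return float(np.mean(vals)), float(np.std(vals, ddof=0))


@dataclass
class TrajectoryPoint:
    timepoint: float
    n_genuine: int
    retention: float
    top_clone_fraction: float


def diversity_trajectory(
    ts: PoolTimeSeries, call_params: ClusteringParams = ClusteringParams()
) -> List[TrajectoryPoint]:
    """Genuine-barcode counts, retention vs t0, and dominant-clone fraction.

    Uses knee-filtered (genuine) barcodes at every timepoint, so sequencing
    error background does not masquerade as diversity.
    """
    points: List[TrajectoryPoint] = []
    baseline: Optional[int] = None
    for t, table in zip(ts.timepoints, ts.tables):
        res = call_genuine(table, call_params)
        n = len(res.genuine)
        if baseline is None:
            baseline = n
        total = res.clustered_counts.total
        top = max(res.clustered_counts.counts.values()) / total if total else 0.0
        points.append(
            TrajectoryPoint(
                timepoint=t,
                n_genuine=n,
                retention=n / baseline if baseline else 0.0,
                top_clone_fraction=float(top),
            )
        )
    return points


def rmce_efficiency(genuine_count: int, transfected_cells: int) -> float:
    """Fraction of transfected cells yielding a surviving integrant clone."""
    if transfected_cells <= 0:
        raise ValueError("transfected_cells must be > 0")
    if genuine_count < 0:
        raise ValueError("genuine_count must be >= 0")
    return genuine_count / transfected_cells
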