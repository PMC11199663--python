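"""Lineage-aware clone screening analytics.

Clones sharing a barcode ("sibling clones") descend from one integration
event; clones with cohort-unique barcodes ("relative clones") come from
independent events.  This module classifies lineages, compares pairwise
absolute phenotype differences between the two groups (Wilcoxon rank-sum,
BH-FDR across phenotypes), designs diversity enrichment/depletion screening
arms, and runs the max-titer-versus-screening-depth subsampling simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CloneRecord:
    clone_id: str
    barcode: str
    phenotypes: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError("barcode must be non-empty")


@dataclass
class LineageGroups:
    """siblings: barcode -> clones (multiplicity >= threshold); relatives: unique-barcode clones."""

    siblings: Dict[str, List[CloneRecord]]
    relatives: List[CloneRecord]
    sibling_min: int = 3

    @property
    def n_sibling_clones(self) -> int:
        return sum(len(g) for g in self.siblings.values())


def classify_lineages(cohort: Sequence[CloneRecord], sibling_min: int = 3) -> LineageGroups:
    """Partition a cohort by barcode multiplicity.

    Barcodes occurring >= sibling_min times form sibling groups; barcodes
    occurring exactly once are relatives; intermediate multiplicities belong
    to neither group.
    """
    if not cohort:
        raise ValueError("empty cohort")
    by_bc: Dict[str, List[CloneRecord]] = {}
    for rec in cohort:
        by_bc.setdefault(rec.barcode, []).append(rec)
    siblings = {bc: g for bc, g in by_bc.items() if len(g) >= sibling_min}
    relatives = [g[0] for g in by_bc.values() if len(g) == 1]
    return LineageGroups(siblings=siblings, relatives=relatives, sibling_min=sibling_min)


@dataclass
class PairwiseTestResult:
    phenotype: str
    statistic: float
    pvalue: float
    sibling_mean_diff: float
    relative_mean_diff: float
    n_sibling_pairs: int
    n_relative_pairs: int


def _pairs_abs_diff(values: Sequence[float]) -> List[float]:
    return [abs(a - b) for a, b in combinations(values, 2)]


def pairwise_difference_test(groups: LineageGroups, phenotype: str) -> PairwiseTestResult:
    """Rank-sum test of |Δphenotype| for within-sibling vs relative pairs.

    Sibling differences are pooled across groups but pairs are only formed
    within a group; relative differences use all pairs among unique-barcode
    clones.  Two-sided Wilcoxon rank-sum (exact when the combined sample is
    small and untied, otherwise normal approximation with continuity and tie
    correction).
    """
    sib_diffs: List[float] = []
    for group in groups.siblings.values():
        sib_diffs.extend(_pairs_abs_diff([c.phenotypes[phenotype] for c in group]))
    rel_diffs = _pairs_abs_diff([c.phenotypes[phenotype] for c in groups.relatives])
    if len(sib_diffs) < 2 or len(rel_diffs) < 2:
        raise ValueError(f"degenerate comparison sets for phenotype {phenotype!r}")
    n = len(sib_diffs) + len(rel_diffs)
    has_ties = len(set(sib_diffs + rel_diffs)) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(sib_diffs, rel_diffs, alternative="two-sided", method=method)
    return PairwiseTestResult(
        phenotype=phenotype,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        sibling_mean_diff=float(np.mean(sib_diffs)),
        relative_mean_diff=float(np.mean(rel_diffs)),
        n_sibling_pairs=len(sib_diffs),
        n_relative_pairs=len(rel_diffs),
    )


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_phenotypes(
    groups: LineageGroups, phenotypes: Sequence[str]
) -> pd.DataFrame:
    """Per-phenotype sibling-vs-relative tests with FDR across phenotypes."""
    results = [pairwise_difference_test(groups, ph) for ph in phenotypes]
    df = pd.DataFrame([vars(r) for r in results])
    df["qvalue"] = fdr_adjust(df["pvalue"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# screening-arm design


@dataclass
class ScreeningArms:
    enrichment: List[CloneRecord]
    depletion: List[CloneRecord]

    @property
    def enrichment_barcodes(self) -> int:
        return len({c.barcode for c in self.enrichment})

    @property
    def depletion_barcodes(self) -> int:
        return len({c.barcode for c in self.depletion})


def design_arms(
    cohort: Sequence[CloneRecord],
    arm_size: int = 48,
    n_lineages_depletion: int = 15,
    seed: Optional[int] = None,
) -> ScreeningArms:
    """Diversity-enriched and diversity-depleted screening arms.

    The enrichment arm holds ``arm_size`` clones with pairwise-distinct
    barcodes; the depletion arm holds ``arm_size`` clones drawn from exactly
    ``n_lineages_depletion`` barcodes (largest lineages first), each lineage
    represented at least once.
    """
    rng = np.random.default_rng(seed)
    by_bc: Dict[str, List[CloneRecord]] = {}
    for rec in cohort:
        by_bc.setdefault(rec.barcode, []).append(rec)
    barcodes = sorted(by_bc)
    if len(barcodes) < arm_size:
        raise ValueError(
            f"enrichment arm infeasible: {len(barcodes)} distinct barcodes < arm_size {arm_size}"
        )
    # enrichment: random distinct barcodes, one random clone each
    chosen = rng.choice(len(barcodes), size=arm_size, replace=False)
    enrichment = [
        by_bc[barcodes[i]][rng.integers(len(by_bc[barcodes[i]]))] for i in sorted(chosen)
    ]

    # depletion: largest lineages (ties broken by barcode) until arm covered
    ranked = sorted(barcodes, key=lambda b: (-len(by_bc[b]), b))
    if len(ranked) < n_lineages_depletion:
        raise ValueError(
            f"depletion arm infeasible: {len(ranked)} lineages < {n_lineages_depletion}"
        )
    lineages = ranked[:n_lineages_depletion]
    capacity = sum(len(by_bc[b]) for b in lineages)
    if capacity < arm_size:
        raise ValueError(
            f"depletion arm infeasible: top {n_lineages_depletion} lineages hold "
            f"{capacity} clones < arm_size {arm_size}"
        )
    depletion: List[CloneRecord] = []
    remaining: List[CloneRecord] = []
    for b in lineages:
        members = list(by_bc[b])
        pick = int(rng.integers(len(members)))
        depletion.append(members.pop(pick))
        remaining.extend(members)
    extra = rng.choice(len(remaining), size=arm_size - len(depletion), replace=False)
    depletion.extend(remaining[i] for i in sorted(extra))
    return ScreeningArms(enrichment=enrichment, depletion=depletion)


def max_titer_curve(
    titers: Sequence[float],
    depths: Sequence[int],
    replicates: int = 3,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Maximum titer reached when screening n randomly picked clones.

    For each depth n, draw n titers without replacement ``replicates`` times
    independently and record the subset maximum; returns per-depth mean and
    SD of the maxima.
    """
    titers = np.asarray(titers, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        depth = int(depth)
        if not 1 <= depth <= len(titers):
            raise ValueError(f"depth {depth} outside [1, {len(titers)}]")
        maxima = [
            float(rng.choice(titers, size=depth, replace=False).max())
            for _ in range(replicates)
        ]
        sd = float(np.std(maxima, ddof=1)) if replicates > 1 else 0.0
        rows.append({"depth": depth, "max_titer_mean": float(np.mean(maxima)), "max_titer_sd": sd})
    return pd.DataFrame(rows)
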