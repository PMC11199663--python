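"""Lineage-aware clone screening: sibling variance test, arms, titer curves.

Simulates a 67-clone cohort with lineage structure (between-lineage SD five
times the within-lineage SD), tests whether sibling clones are phenotypically
closer than relative clones, designs diversity enrichment/depletion arms and
compares their max-titer-versus-screening-depth curves.
"""

from clonotrace import (
    classify_lineages,
    design_arms,
    max_titer_curve,
    screen_phenotypes,
    simulate_phenotypes,
)

barcodes = [f"S{i % 9}" for i in range(34)] + [f"U{i}" for i in range(33)]
barcodes_pool = [f"S{i % 15}" for i in range(80)] + [f"U{i}" for i in range(55)]

cohort = simulate_phenotypes(
    barcodes,
    phenotypes={"titer": (2000.0, 400.0, 80.0), "vcd": (12.0, 2.0, 0.4)},
    seed=4,
)
groups = classify_lineages(cohort, sibling_min=3)
print(f"{groups.n_sibling_clones} sibling clones in {len(groups.siblings)} lineages, "
      f"{len(groups.relatives)} relative clones")

df = screen_phenotypes(groups, ["titer", "vcd"])
print(df[["phenotype", "sibling_mean_diff", "relative_mean_diff", "pvalue", "qvalue"]]
      .round(4).to_string(index=False))
print("Sibling pairs show smaller |differences| -> phenotype is largely set by")
print("the integration lineage, so screening should maximize lineage diversity.\n")

pool = simulate_phenotypes(barcodes_pool, phenotypes={"titer": (2000.0, 400.0, 40.0)}, seed=5)
arms = design_arms(pool, arm_size=48, n_lineages_depletion=15, seed=5)
print(f"enrichment arm: 48 clones / {arms.enrichment_barcodes} barcodes; "
      f"depletion arm: 48 clones / {arms.depletion_barcodes} barcodes")

for name, arm in (("enrichment", arms.enrichment), ("depletion", arms.depletion)):
    titers = [c.phenotypes["titer"] for c in arm]
    curve = max_titer_curve(titers, depths=[4, 8, 16, 32, 48], replicates=3, seed=6)
    print(f"\n{name} arm max-titer curve:")
    print(curve.round(1).to_string(index=False))
print("\nThe diverse (enrichment) arm reaches a higher maximum titer at lower")
print("screening depth: fewer clones need to be screened to find the top producer.")
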