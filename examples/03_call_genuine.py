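"""Call genuine clone barcodes in a contaminated well.

Simulates a 1:100 two-clone mixture sequenced to 500k merged reads with
0.1%/base substitution errors, then runs Levenshtein-1 clustering and the
knee-point threshold, and checks the well against an expected clone number.
"""

import numpy as np

from clonotrace import FLANKS, call_genuine, count_merged, cross_contamination_report
from clonotrace.simulate import random_barcodes, simulate_merged_reads

rng = np.random.default_rng(3)
major, minor = random_barcodes(2, 15, rng)
seqs = simulate_merged_reads({major: 100, minor: 1}, 500_000, FLANKS["M1"], 1e-3, seed=3)
table, _ = count_merged(seqs.items(), FLANKS["M1"])
print(f"raw table: {len(table)} distinct barcodes from {table.reads_extracted} reads")

result = call_genuine(table)
print(f"after clustering: {len(result.clustered_counts)} barcodes; "
      f"knee threshold {result.threshold}")
print(f"genuine barcodes: {len(result.genuine)}")

report = cross_contamination_report(result, expected_n=1)
print(f"\nexpected 1 clone -> contamination check {'pass' if report.passed else 'FAIL'}")
for bc, frac in report.fractions.items():
    label = "major" if bc == major else ("minor" if bc == minor else "?")
    print(f"  {bc}  fraction {frac:.4f}  ({label})")
print("\nThe minor clone survives the knee filter at ~1% abundance, so a 1:100")
print("cross-contamination is detected even against sequencing-error background.")
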