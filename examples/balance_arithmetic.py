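"""Class-imbalance arithmetic of the 39-database reference corpus.

Reproduces, from the closed form, the balanced per-class training counts:
each class keeps ~70% of its rows for training (banker's rounding) and is
topped up by SMOTE to the target T = ceiling of the mean class count.
"""

import math

from bioidkit import (
    REFERENCE_CLASS_COUNTS,
    balanced_train_count,
    default_target,
    imbalance_ratio,
)

T = default_target(REFERENCE_CLASS_COUNTS)
print(f"per-class target T = {T}  (ceiling mean of {len(REFERENCE_CLASS_COUNTS)} classes)")

for name in ["Rfam", "Ensembl exon", "HGNC"]:
    n = REFERENCE_CLASS_COUNTS[name]
    print(f"{name:14s} original {n:>8,d} -> balanced train {balanced_train_count(n, T):>8,d}")

before = imbalance_ratio(REFERENCE_CLASS_COUNTS)
after = imbalance_ratio(
    {k: balanced_train_count(n, T) for k, n in REFERENCE_CLASS_COUNTS.items()}
)
print(f"majority/minority ratio: {math.floor(before):,}:1 before, {after:.1f}:1 after")
# The ratio collapses from ~14,702:1 to ~12:1: minority classes are raised to
# T while majority classes keep their plain 70% split.
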