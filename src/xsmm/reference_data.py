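"""Published summary tables of the GSE9531 cross-species hybridization study.

These are the printed probe-pair counts and group-contrast p-values from the
HGU133plus2.0 (human) vs Rhesus Macaque GeneChip experiment whose design this
pipeline follows (10 + 10 arrays, five tissue sources, two replicates each;
15,800 single-base mismatch probe pairs mined from the two designs).  They
are consumed as *inputs* by the aggregation paths — the raw .CEL data needed
to recompute them is deliberately out of scope.
"""

from __future__ import annotations

import pandas as pd

#: Number of PM/MM_i probe pairs found at each of the 25 mismatch positions.
POSITION_PAIR_COUNTS = {
    1: 689, 2: 614, 3: 678, 4: 644, 5: 590, 6: 672, 7: 667, 8: 639,
    9: 682, 10: 587, 11: 596, 12: 533, 13: 521, 14: 540, 15: 547,
    16: 559, 17: 642, 18: 633, 19: 630, 20: 622, 21: 686, 22: 667,
    23: 652, 24: 763, 25: 747,
}

#: Per-mismatch-type group-contrast p-values (pooled-variance Student's
#: t-tests between the 5' end, center and 3' end position groups) and pair
#: frequencies, as published.
TYPE_GROUP_TESTS = pd.DataFrame(
    [
        # type, center vs 5', center vs 3', 5' vs 3', frequency
        ("A-C", 0.00187, 0.000128, 0.525, 673),
        ("A-G", 6.29e-05, 6.78e-10, 0.0423, 2567),
        ("A-T", 2.78e-08, 8.31e-10, 0.747, 553),
        ("T-A", 0.0821, 0.00499, 0.328, 506),
        ("T-C", 0.00733, 0.047, 0.461, 2920),
        ("T-G", 0.553, 0.185, 0.422, 435),
        ("C-A", 0.187, 2.54e-09, 1.89e-06, 778),
        ("C-G", 0.000115, 3.10e-06, 0.377, 627),
        ("C-T", 1.47e-14, 2.13e-46, 1.66e-12, 2874),
        ("G-A", 2.17e-06, 8.23e-19, 6.08e-05, 2624),
        ("G-C", 0.00103, 2.76e-05, 0.339, 687),
        ("G-T", 0.0126, 5.62e-05, 0.103, 556),
    ],
    columns=[
        "mismatch_type",
        "p_center_vs_five_prime",
        "p_center_vs_three_prime",
        "p_five_prime_vs_three_prime",
        "frequency",
    ],
)
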