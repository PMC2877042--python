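"""Estimate log2(PM/MM_i) effects and summarize them.

Writes the per-pair estimates, the 25-position profile, the MAD-on-median
spread regression, the 12-type x 3-group summary with t-tests, and the
per-position comparison against identical-probe controls; prints the
headline numbers (peak position, flank contrasts, group excesses).
"""

import pandas as pd

from xsmm.effect_stats import contrast_percent

from common import OUTDIR, runner

if __name__ == "__main__":
    r = runner()
    r.analyze()
    r.write_manifest()
    print(r.log[-1])

    profile = pd.read_csv(f"{OUTDIR}/position_profile.tsv", sep="\t").set_index("position")
    means = profile["mean"]
    peak = int(means.idxmax())
    print(f"positional mean peaks at position {peak}")
    print(
        "PM/MM ratio decrease peak -> position 1: "
        f"{contrast_percent(means.loc[peak], means.loc[1], 'ratio'):.1f}%"
    )
    print(
        "PM/MM ratio decrease peak -> position 25: "
        f"{contrast_percent(means.loc[peak], means.loc[25], 'ratio'):.1f}%"
    )
    reg = pd.read_csv(f"{OUTDIR}/spread_regression.tsv", sep="\t").iloc[0]
    print(
        f"MAD on median regression: slope {reg['slope']:.3f}, "
        f"R^2 {reg['r_squared']:.3f}"
    )
    summary = pd.read_csv(f"{OUTDIR}/type_group_summary.tsv", sep="\t")
    center_excess = (
        (summary["mean_center"] > summary["mean_five_prime"])
        & (summary["mean_center"] > summary["mean_three_prime"])
    ).sum()
    print(f"center group exceeds both flanks for {center_excess}/12 types")
    flank = (summary["p_five_prime_vs_three_prime"] > 0.05).sum()
    print(f"5'-end vs 3'-end contrasts with p > 0.05: {flank}/12")
    controls = pd.read_csv(f"{OUTDIR}/control_tests.tsv", sep="\t")
    print(f"max p vs identical-probe controls across positions: {controls['p'].max():.2e}")
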