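#!/usr/bin/env python
"""Reliability banding and per-platform summary of the twin-model results.

Bands the MZ correlations (excellent >= 0.75, good 0.60-0.74, moderate
0.40-0.59, indeterminate < 0.40) and tabulates per-platform means and
ranges of the twin correlations and heritability, split by model class.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import twinmetab as tm
from twinmetab.io import read_table, write_table
from twinmetab.summarize import classify_reliability_table, platform_summary

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    results = read_table(RESULTS / "04_twin_results.tsv")
    banded = classify_reliability_table(results)
    write_table(
        banded[["metabolite", "platform", "r_mz", "band"]],
        RESULTS / "05_reliability.tsv",
    )
    summary = platform_summary(results)
    write_table(summary, RESULTS / "05_platform_summary.tsv")

    frac = tm.moderate_or_better_fraction(results)
    print(f"moderate-or-better reliability: {100 * frac:.1f}% of "
          f"{len(results)} metabolites")
    for _, row in summary.iterrows():
        parts = [f"{row.platform}: r_MZ mean {row.r_mz_mean:.2f} "
                 f"({row.r_mz_min:.2f}-{row.r_mz_max:.2f})"]
        if "ade_h2_mean" in row and row.notna().get("ade_h2_mean", False):
            parts.append(f"broad h2 {row.ade_h2_mean:.2f} "
                         f"({row.ade_h2_min:.2f}-{row.ade_h2_max:.2f}, "
                         f"n={int(row.get('n_ade', 0))})")
        if "ace_h2_mean" in row and row.notna().get("ace_h2_mean", False):
            parts.append(f"narrow h2 {row.ace_h2_mean:.2f} "
                         f"({row.ace_h2_min:.2f}-{row.ace_h2_max:.2f}, "
                         f"n={int(row.get('n_ace', 0))})")
        print("  " + "; ".join(parts))


if __name__ == "__main__":
    main()
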