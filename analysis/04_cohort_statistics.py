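#!/usr/bin/env python
"""Cohort statistics.

Two parts.  (1) Worked examples computed from the published per-type
summaries of the 128-eye cohort: pooled EZ-disruption rates and pooled CST
for eyes without vs with Segment-2 fluid, with their χ² / Student-t tests,
plus the taxonomy structure, type fractions and pooled ERM incidence.
(2) The per-type comparison report for the simulated cohort written by
03_classify_cohort.py (if present), saved as results/table_report.json.
"""

import json
from pathlib import Path

from enfacedme import reference as ref
from enfacedme.cohort import read_cohort
from enfacedme.stats import (
    chi_square_independence,
    pooled_mean_sd,
    pooled_proportion,
    table2_report,
    two_sample_t,
)
from enfacedme.taxonomy import OBSERVED_TYPES, enumerate_taxonomy

OUT = Path(__file__).resolve().parents[1] / "results"


def published_examples():
    dry = [ref.ez_counts(t) for t in ref.SEGMENT2_DRY_TYPES]
    wet = [ref.ez_counts(t) for t in ref.SEGMENT2_WET_TYPES]
    p_dry, p_wet = pooled_proportion(dry), pooled_proportion(wet)
    print("pooled EZ disruption:  "
          f"dry {100 * p_dry:.1f}%  wet {100 * p_wet:.1f}%")
    e1, n1 = sum(e for e, _ in dry), sum(n for _, n in dry)
    e2, n2 = sum(e for e, _ in wet), sum(n for _, n in wet)
    stat, df, p = chi_square_independence([[e1, n1 - e1], [e2, n2 - e2]])
    print(f"  chi2 = {stat:.2f} (df={df}), p = {p:.2e}")

    cst_dry = pooled_mean_sd([ref.cst_summary(t) for t in ref.SEGMENT2_DRY_TYPES])
    cst_wet = pooled_mean_sd([ref.cst_summary(t) for t in ref.SEGMENT2_WET_TYPES])
    print(f"pooled CST: dry {cst_dry.mean:.2f} ± {cst_dry.sd:.2f} μm (n={cst_dry.n})  "
          f"wet {cst_wet.mean:.2f} ± {cst_wet.sd:.2f} μm (n={cst_wet.n})")
    t, df, p = two_sample_t(cst_dry, cst_wet, "pooled")
    print(f"  Student t = {t:.2f}, p = {p:.2e}")

    labels = enumerate_taxonomy()
    counts = ref.type_counts()
    total = sum(counts.values())
    print(f"taxonomy: {len(labels)} combinations, "
          f"{sum(l in OBSERVED_TYPES for l in labels)} observed types")
    fractions = "  ".join(f"{t} {100 * counts[t] / total:.1f}%" for t in ref.TYPE_ORDER)
    print(f"type fractions (n={total}): {fractions}")
    erm = pooled_proportion([(ref.PUBLISHED_COHORT[t]["n_erm"], counts[t])
                             for t in ref.TYPE_ORDER])
    print(f"pooled ERM incidence: {100 * erm:.1f}%")


def simulated_report():
    path = OUT / "cohort.csv"
    if not path.exists():
        print("\n(no simulated cohort found; run 03_classify_cohort.py first)")
        return
    cohort = read_cohort(path)
    report = table2_report(cohort)
    out = OUT / "table_report.json"
    out.write_text(json.dumps(report, indent=1, default=float))
    print(f"\nsimulated cohort report ({report['n_total']} eyes) -> {out}")
    for label, block in report["types"].items():
        cst = block.get("cst_um", (float("nan"), 0.0))
        print(f"  {label:10s} n={block['n']:2d} ({block['pct']:.1f}%)  "
              f"CST {cst[0]:.0f} ± {cst[1]:.0f} μm")
    pooled = report.get("segment2_pooled", {})
    if "cst_um" in pooled:
        print(f"  Segment-2 dry vs wet CST p = {pooled['cst_um']['p']:.3g}; "
              f"EZ chi2 p = {pooled['ez_disrupted']['p']:.3g}")


def main():
    published_examples()
    simulated_report()


if __name__ == "__main__":
    main()
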