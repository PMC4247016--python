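"""Transposon coverage vs expression and DNA methylation.

Summarizes small-RNA coverage per transposable element as RPKM, bins it
(low < 5, middle 5-10, high > 10), and runs the association battery:
one-sided Mann-Whitney U (is coverage higher on silent elements?),
Spearman/Pearson correlation between methylation level and coverage, and
the 5' nucleotide composition of TE-derived reads (expected ~60% U at
position 1).
"""

import json

from srnascape import SyntheticConfig, generate
from srnascape.categories import assign_category
from srnascape.io_coverage import in_range
from srnascape.te_meth import (
    association_tests,
    five_prime_composition,
    region_stats_table,
    stats_to_frame,
)

bundle = generate(SyntheticConfig(seed=17))
reads = in_range(bundle.all_reads())
expr = bundle.expression
gene_ref = expr.loc[expr["kind"] == "gene", "rnaseq"].tolist()

stats = region_stats_table(
    bundle.annotations.repeats, reads, total_aligned=len(reads),
    probes=bundle.annotations.methylation,
    expression=dict(zip(expr["name"], expr["rnaseq"])),
    est_counts=dict(zip(expr["name"], expr["est_count"])),
    reference_expressions=gene_ref,
)
print(stats_to_frame(stats).round(2).to_string(index=False))

report = association_tests(stats)
print("\nMann-Whitney (coverage higher on low/none-expression TEs):",
      f"p = {report['mw_expression']['pvalue']:.2e}")
print("Spearman(methylation, RPKM):", round(report["spearman"]["rho"], 3))
print("Pearson(methylation, RPKM): ", round(report["pearson"]["r"], 3))

te_reads = [r for r in reads if assign_category(r, bundle.annotations) == "repeats"]
comp = five_prime_composition(te_reads)
print("\n5' composition of TE reads (positions 1-5):")
print(comp.round(3).to_string())
print(f"position-1 U frequency: {comp.loc[1, 'U']:.3f} (planted 0.6)")
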