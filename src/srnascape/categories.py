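"""Genomic-category assignment of reads and summary accounting.

Two counting semantics are supported:

* ``partition`` — every read is assigned to exactly one category under a
  configurable priority order (default tRNA > other ncRNA > repeat >
  gene > intergenic); per-category counts sum to the aligned total.
* ``overlap`` — a read is counted in every annotation row it overlaps by
  at least 1 bp (rows need not partition), matching how per-annotation
  summary tables are usually reported for small-RNA data.

Strand is ignored for assignment: TE-derived small RNAs accumulate on
both strands of the element.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_coverage import AlignedRead, AnnotationSet

__all__ = [
    "assign_category",
    "length_distribution",
    "summary_table",
    "DEFAULT_PRIORITY",
    "CATEGORY_LABELS",
]

#: priority order for partition-mode assignment (first match wins)
DEFAULT_PRIORITY = ("trnas", "ncrnas", "repeats", "genes")

CATEGORY_LABELS = {
    "genes": "genes",
    "repeats": "repeat_regions",
    "intergenic": "intergenic",
    "trnas": "tRNA_genes",
    "ncrnas": "other_ncRNAs",
}

LENGTH_RANGE = (18, 36)


def assign_category(
    read: AlignedRead,
    annotations: AnnotationSet,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> str:
    """Single category for a read under the priority order (any-overlap)."""
    for cat in priority:
        if annotations.query(cat, read.chrom, read.start, read.end):
            return cat
    return "intergenic"


def overlap_categories(read: AlignedRead, annotations: AnnotationSet) -> list[str]:
    """All annotation categories the read overlaps (>=1 bp); 'intergenic'
    when it overlaps none."""
    cats = [
        cat
        for cat in ("genes", "repeats", "trnas", "ncrnas")
        if annotations.query(cat, read.chrom, read.start, read.end)
    ]
    return cats or ["intergenic"]


def length_distribution(
    reads: Iterable[AlignedRead],
    by: str = "library",
    annotations: Optional[AnnotationSet] = None,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Read-length histogram, grouped by library or by genomic category.

    Returns a DataFrame indexed by length (18-36 nt) with one column per
    group; cells are read counts.
    """
    if by not in ("library", "category"):
        raise ValueError("by must be 'library' or 'category'")
    counts: Counter = Counter()
    for r in reads:
        if by == "library":
            group = r.library or "all"
        else:
            if annotations is None:
                raise ValueError("annotations required to group by category")
            group = assign_category(r, annotations, priority)
        counts[(r.length, group)] += 1
    lengths = range(LENGTH_RANGE[0], LENGTH_RANGE[1] + 1)
    groups = sorted({g for (_, g) in counts})
    data = {g: [counts.get((l, g), 0) for l in lengths] for g in groups}
    return pd.DataFrame(data, index=pd.Index(lengths, name="length"))


def summary_table(
    reads_per_library: Mapping[str, Sequence[AlignedRead]],
    annotations: AnnotationSet,
    mode: str = "partition",
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Per-library category accounting.

    Rows: aligned totals, then per-category counts and fractions of
    aligned reads.  ``mode='partition'`` assigns each read once by
    priority; ``mode='overlap'`` counts a read in every annotation row it
    touches, so rows need not sum to the total.
    """
    if mode not in ("partition", "overlap"):
        raise ValueError("mode must be 'partition' or 'overlap'")
    libs = list(reads_per_library)
    cats = ["genes", "repeats", "intergenic", "trnas", "ncrnas"]
    counts = {lib: Counter() for lib in libs + ["total"]}
    totals = Counter()
    for lib in libs:
        for r in reads_per_library[lib]:
            if r.out_of_range:
                continue
            totals[lib] += 1
            totals["total"] += 1
            if mode == "partition":
                assigned = [assign_category(r, annotations, priority)]
            else:
                assigned = overlap_categories(r, annotations)
            for cat in assigned:
                counts[lib][cat] += 1
                counts["total"][cat] += 1
    rows = []
    index = []
    index.append("aligned")
    rows.append({c: totals[c] for c in libs + ["total"]})
    for cat in cats:
        index.append(f"{CATEGORY_LABELS[cat]}_count")
        rows.append({c: counts[c][cat] for c in libs + ["total"]})
        index.append(f"{CATEGORY_LABELS[cat]}_fraction")
        rows.append(
            {
                c: (counts[c][cat] / totals[c]) if totals[c] else 0.0
                for c in libs + ["total"]
            }
        )
    return pd.DataFrame(rows, index=pd.Index(index, name="row"))
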