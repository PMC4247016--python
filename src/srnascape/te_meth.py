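"""Per-region coverage, methylation and expression statistics for TEs/genes.

Summaries follow common small-RNA practice: coverage is expressed as RPKM
(reads per kilobase of region per million aligned reads, computed from
multimapper-reweighted counts by default), methylation level of a region
is the proportion of overlapping probes called methylated, and expression
is dichotomized at the 15th percentile of all values ("low") to separate
silent from transcribed regions.  The association statistics are the
one-sided Mann-Whitney U test (sRNA coverage on low/none vs expressed
regions), Spearman and Pearson correlations between methylation level and
RPKM, and the pairwise inter-library correlation of coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_coverage import AlignedRead, Feature

__all__ = [
    "RegionStats",
    "rpkm",
    "region_read_count",
    "methylation_level",
    "bin_rpkm",
    "expression_class",
    "association_tests",
    "five_prime_composition",
    "region_stats_table",
]

#: RPKM bin edges; both boundaries fall in the middle bin so that bins
#: are exhaustive (the verbal definition uses strict inequalities)
RPKM_LOW_MAX = 5.0
RPKM_HIGH_MIN = 10.0
LOW_EXPRESSION_PERCENTILE = 15.0
#: minimal region length for TE analyses / for family summaries
MIN_TE_LENGTH = 50
MIN_FAMILY_TE_LENGTH = 300


@dataclass
class RegionStats:
    """Coverage/methylation/expression summary of one genomic region."""

    chrom: str
    start: int
    end: int
    name: str = ""
    family: str = ""
    srna_rpkm: float = 0.0
    methylation_level: Optional[float] = None  # None = no probes (flagged)
    expression: Optional[float] = None
    est_count: Optional[float] = None
    expression_class: str = ""
    rpkm_bin: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def region_read_count(
    region: tuple[str, int, int] | Feature,
    reads: Iterable[AlignedRead],
    weighted: bool = True,
) -> float:
    """Sum of (re)weighted reads overlapping the region by >= 1 bp."""
    chrom, start, end = (
        (region.chrom, region.start, region.end)
        if isinstance(region, Feature)
        else region
    )
    total = 0.0
    for r in reads:
        if r.chrom == chrom and r.start < end and start < r.end:
            total += r.weight if weighted else 1.0
    return total


def rpkm(count: float, region_length: int, total_aligned: float) -> float:
    """Reads per kilobase of region per million aligned reads.

    rpkm = count * 1e9 / (length_nt * total_aligned).  Invariant under
    jointly scaling count and total (sequencing depth).
    """
    if region_length <= 0:
        raise ValueError("zero-length region")
    if total_aligned <= 0:
        raise ValueError("total_aligned must be positive")
    return count * 1e9 / (region_length * total_aligned)


def methylation_level(
    region: tuple[str, int, int] | Feature,
    probes: Sequence[Feature],
) -> Optional[float]:
    """Fraction of probes overlapping the region that are called methylated.

    Returns None (undefined flag) when no probe overlaps the region.
    """
    chrom, start, end = (
        (region.chrom, region.start, region.end)
        if isinstance(region, Feature)
        else region
    )
    overlapping = [
        p for p in probes if p.chrom == chrom and p.start < end and start < p.end
    ]
    if not overlapping:
        return None
    meth = sum(int(p.attrs.get("methylated", 0)) for p in overlapping)
    return meth / len(overlapping)


def bin_rpkm(value: float) -> str:
    """'low' (< 5), 'middle' ([5, 10]) or 'high' (> 10) sRNA coverage."""
    if value < RPKM_LOW_MAX:
        return "low"
    if value <= RPKM_HIGH_MIN:
        return "middle"
    return "high"


def expression_class(
    expressions: Sequence[float],
    percentile: float = LOW_EXPRESSION_PERCENTILE,
    reference: Optional[Sequence[float]] = None,
) -> list[str]:
    """Label each value 'low' (<= the given percentile) or 'expressed'.

    The percentile threshold is computed over ``reference`` when given
    (e.g. all gene expressions, then applied to TEs), else over the
    values themselves.
    """
    values = np.asarray(expressions, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one expression value")
    ref = np.asarray(reference, dtype=float) if reference is not None else values
    threshold = float(np.percentile(ref, percentile))
    return ["low" if v <= threshold else "expressed" for v in values]


def five_prime_composition(
    reads: Iterable[AlignedRead], n_positions: int = 5
) -> pd.DataFrame:
    """Base frequencies at read positions 1..n (read orientation, T -> U).

    Rows are positions (1-based), columns A/C/G/U; each row sums to 1
    over reads long enough to have that position.
    """
    counts = np.zeros((n_positions, 4), dtype=float)
    bases = "ACGU"
    index = {b: i for i, b in enumerate(bases)}
    for r in reads:
        if not r.sequence:
            continue
        seq = r.sequence.upper().replace("T", "U")
        for pos in range(min(n_positions, len(seq))):
            i = index.get(seq[pos])
            if i is not None:
                counts[pos, i] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freq = counts / totals
    return pd.DataFrame(
        freq, index=pd.Index(range(1, n_positions + 1), name="position"),
        columns=list(bases),
    )


def _mannwhitney_one_sided(
    greater: Sequence[float], lesser: Sequence[float]
) -> tuple[float, float]:
    """One-sided Mann-Whitney U: H1 = first sample stochastically greater.

    Exact distribution when n+m <= 20 and no ties; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(greater, dtype=float)
    y = np.asarray(lesser, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def association_tests(
    regions: Sequence[RegionStats],
    reads_per_library: Optional[Mapping[str, Sequence[AlignedRead]]] = None,
    min_group: int = 3,
) -> dict:
    """The coverage/expression/methylation association battery.

    Returns a dict with:

    * ``mw_expression``: one-sided Mann-Whitney U and p for sRNA RPKM on
      low/none-expression regions vs expressed regions (H1: higher on
      silent regions);
    * ``mw_methylation``: same test for methylated (level > 0.5) vs
      unmethylated regions;
    * ``spearman`` / ``pearson``: correlation between methylation level
      and RPKM over regions with defined methylation;
    * ``library_correlation``: pairwise Spearman matrix of per-region
      weighted read counts between libraries (when reads are given).

    Groups smaller than ``min_group`` yield NA with a warning field.
    """
    report: dict = {"warnings": []}

    low = [r.srna_rpkm for r in regions if r.expression_class == "low"]
    expressed = [r.srna_rpkm for r in regions if r.expression_class == "expressed"]
    if len(low) >= min_group and len(expressed) >= min_group:
        u, p = _mannwhitney_one_sided(low, expressed)
        report["mw_expression"] = {"U": u, "pvalue": p, "n_low": len(low),
                                   "n_expressed": len(expressed)}
    else:
        report["mw_expression"] = None
        report["warnings"].append(
            f"expression groups too small for Mann-Whitney "
            f"(low={len(low)}, expressed={len(expressed)})"
        )

    with_meth = [r for r in regions if r.methylation_level is not None]
    meth = [r.srna_rpkm for r in with_meth if r.methylation_level > 0.5]
    unmeth = [r.srna_rpkm for r in with_meth if r.methylation_level <= 0.5]
    if len(meth) >= min_group and len(unmeth) >= min_group:
        u, p = _mannwhitney_one_sided(meth, unmeth)
        report["mw_methylation"] = {"U": u, "pvalue": p, "n_methylated": len(meth),
                                    "n_unmethylated": len(unmeth)}
    else:
        report["mw_methylation"] = None
        report["warnings"].append(
            f"methylation groups too small for Mann-Whitney "
            f"(methylated={len(meth)}, unmethylated={len(unmeth)})"
        )

    if len(with_meth) >= min_group:
        mlev = np.array([r.methylation_level for r in with_meth])
        cov = np.array([r.srna_rpkm for r in with_meth])
        if np.ptp(mlev) > 0 and np.ptp(cov) > 0:
            rho, rho_p = stats.spearmanr(mlev, cov)
            pear, pear_p = stats.pearsonr(mlev, cov)
            report["spearman"] = {"rho": float(rho), "pvalue": float(rho_p)}
            report["pearson"] = {"r": float(pear), "pvalue": float(pear_p)}
        else:
            report["spearman"] = report["pearson"] = None
            report["warnings"].append("constant methylation or coverage; correlation undefined")
    else:
        report["spearman"] = report["pearson"] = None
        report["warnings"].append("too few regions with methylation probes")

    if reads_per_library:
        libs = sorted(reads_per_library)
        counts = {
            lib: [
                region_read_count((r.chrom, r.start, r.end), reads_per_library[lib])
                for r in regions
            ]
            for lib in libs
        }
        mat = pd.DataFrame(index=libs, columns=libs, dtype=float)
        for i, a in enumerate(libs):
            for b in libs[i:]:
                if a == b:
                    rho = 1.0
                else:
                    rho = float(stats.spearmanr(counts[a], counts[b]).statistic)
                mat.loc[a, b] = mat.loc[b, a] = rho
        report["library_correlation"] = mat
    return report


def region_stats_table(
    regions: Sequence[Feature],
    reads: Sequence[AlignedRead],
    total_aligned: int,
    probes: Sequence[Feature] = (),
    expression: Optional[Mapping[str, float]] = None,
    est_counts: Optional[Mapping[str, float]] = None,
    weighted: bool = True,
    min_length: int = MIN_TE_LENGTH,
    reference_expressions: Optional[Sequence[float]] = None,
) -> list[RegionStats]:
    """Assemble RegionStats for a set of regions (TEs or genes).

    Regions shorter than ``min_length`` are dropped.  Expression of a
    region is the highest expression of any overlapping gene model when
    an expression map keyed by region name is not directly available.
    """
    out: list[RegionStats] = []
    kept = [f for f in regions if f.length > min_length]
    for f in kept:
        count = region_read_count(f, reads, weighted=weighted)
        rs = RegionStats(
            chrom=f.chrom, start=f.start, end=f.end,
            name=f.name, family=str(f.attrs.get("family", "")),
            srna_rpkm=rpkm(count, f.length, total_aligned),
            methylation_level=methylation_level(f, probes) if probes else None,
            expression=(expression or {}).get(f.name),
            est_count=(est_counts or {}).get(f.name),
        )
        rs.rpkm_bin = bin_rpkm(rs.srna_rpkm)
        out.append(rs)
    with_expr = [r for r in out if r.expression is not None]
    if with_expr:
        labels = expression_class(
            [r.expression for r in with_expr], reference=reference_expressions
        )
        for r, lab in zip(with_expr, labels):
            r.expression_class = lab
    return out


def stats_to_frame(regions: Sequence[RegionStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "name": [r.name for r in regions],
            "family": [r.family for r in regions],
            "length": [r.length for r in regions],
            "srna_rpkm": [r.srna_rpkm for r in regions],
            "rpkm_bin": [r.rpkm_bin for r in regions],
            "methylation_level": [r.methylation_level for r in regions],
            "expression": [r.expression for r in regions],
            "est_count": [r.est_count for r in regions],
            "expression_class": [r.expression_class for r in regions],
        }
    )
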