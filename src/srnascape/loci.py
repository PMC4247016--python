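"""Clustering of aligned reads into sRNA-producing loci.

A locus is a chain of reads in which consecutive reads (by genomic
position, strands pooled) are separated by a gap of less than ``max_gap``
nucleotides, supported by at least ``min_reads`` reads.  Loci are then
classified by their read distribution into the two archetypes seen in
small-RNA data: PILE (near-identical copies of one sequence stacked on a
single strand — the signature of precise processing from a structured
precursor) versus DISTRIBUTED (overlapping reads on both strands over a
long region — the siRNA-like signature of transposons and methylated
genes).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_coverage import AlignedRead, AnnotationSet

__all__ = [
    "SrnaLocus",
    "CandidateLocus",
    "cluster_srna_loci",
    "classify_distribution",
    "filter_candidates",
    "merge_across_libraries",
    "shannon_entropy",
]

DEFAULT_MAX_GAP = 100
DEFAULT_MIN_READS = 10
#: minimal fraction of reads on the majority strand for a PILE call
DEFAULT_STRAND_FRACTION = 0.9
#: minimal fraction of 5' ends within +-2 nt of the modal 5' end
DEFAULT_LOCALIZATION = 0.8
LOCALIZATION_SLACK = 2
#: candidate dominant-length window, nt
CANDIDATE_LENGTH_RANGE = (19, 29)
#: consensus entropy threshold, bits per nt
ENTROPY_MIN_BITS = 1.5
DINUCLEOTIDE_MAX_FRACTION = 0.6


@dataclass
class SrnaLocus:
    """A clustered sRNA-producing region and its distribution statistics."""

    chrom: str
    start: int
    end: int
    reads: list[AlignedRead] = field(default_factory=list, repr=False)
    library: str = ""

    @property
    def read_count(self) -> int:
        return len(self.reads)

    @property
    def weighted_count(self) -> float:
        return sum(r.weight for r in self.reads)

    @property
    def strand(self) -> str:
        return "+" if sum(r.strand == "+" for r in self.reads) * 2 >= len(self.reads) else "-"

    @property
    def strand_fraction(self) -> float:
        n_plus = sum(r.strand == "+" for r in self.reads)
        return max(n_plus, len(self.reads) - n_plus) / len(self.reads)

    @property
    def dominant_length(self) -> int:
        counts = Counter(r.length for r in self.reads)
        best = max(counts.values())
        # ties broken toward the shorter length (determinism)
        return min(l for l, c in counts.items() if c == best)

    @property
    def modal_five_prime(self) -> int:
        counts = Counter(r.five_prime() for r in self.reads)
        best = max(counts.values())
        return min(p for p, c in counts.items() if c == best)

    @property
    def localization(self) -> float:
        """Fraction of reads whose 5' end lies within +-2 nt of the mode."""
        mode = self.modal_five_prime
        near = sum(abs(r.five_prime() - mode) <= LOCALIZATION_SLACK for r in self.reads)
        return near / len(self.reads)

    @property
    def libraries(self) -> set[str]:
        return {r.library for r in self.reads if r.library} or (
            {self.library} if self.library else set()
        )


@dataclass
class CandidateLocus:
    """A PILE locus that survived the processed-sRNA candidate filters."""

    locus: SrnaLocus
    passed_filters: dict
    candidate_type: str  # 'tRNA-associated' | 'known-ncRNA' | 'intergenic-novel'
    libraries: set = field(default_factory=set)
    support: int = 1

    @property
    def chrom(self) -> str:
        return self.locus.chrom

    @property
    def start(self) -> int:
        return self.locus.start

    @property
    def end(self) -> int:
        return self.locus.end


def cluster_srna_loci(
    reads: Iterable[AlignedRead],
    max_gap: int = DEFAULT_MAX_GAP,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[SrnaLocus]:
    """Single-linkage clustering of reads along each chromosome.

    Two reads are linked when the gap between them (end-to-start of the
    nearest reads, i.e. overlap counts as gap 0) is ``< max_gap``; a locus
    is any linked chain with ``>= min_reads`` members.  Out-of-range reads
    are excluded.
    """
    by_chrom: dict[str, list[AlignedRead]] = {}
    for r in reads:
        if r.out_of_range:
            continue
        by_chrom.setdefault(r.chrom, []).append(r)
    loci: list[SrnaLocus] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cluster: list[AlignedRead] = []
        cluster_end = -math.inf
        for r in rs:
            if cluster and r.start - cluster_end >= max_gap:
                if len(cluster) >= min_reads:
                    loci.append(_make_locus(chrom, cluster))
                cluster = []
                cluster_end = -math.inf
            cluster.append(r)
            cluster_end = max(cluster_end, r.end)
        if len(cluster) >= min_reads:
            loci.append(_make_locus(chrom, cluster))
    return loci


def _make_locus(chrom: str, members: list[AlignedRead]) -> SrnaLocus:
    return SrnaLocus(
        chrom=chrom,
        start=min(r.start for r in members),
        end=max(r.end for r in members),
        reads=list(members),
    )


def classify_distribution(
    locus: SrnaLocus,
    strand_fraction: float = DEFAULT_STRAND_FRACTION,
    localization: float = DEFAULT_LOCALIZATION,
) -> str:
    """PILE iff the locus is strand-specific and 5'-end localized."""
    if locus.strand_fraction >= strand_fraction and locus.localization >= localization:
        return "PILE"
    return "DISTRIBUTED"


def shannon_entropy(seq: str) -> float:
    """Base-2 Shannon entropy per nucleotide of a sequence."""
    if not seq:
        return 0.0
    counts = Counter(seq.upper())
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def _max_dinucleotide_fraction(seq: str) -> float:
    seq = seq.upper()
    if len(seq) < 2:
        return 1.0
    counts = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
    return max(counts.values()) / (len(seq) - 1)


def filter_candidates(
    loci: Sequence[SrnaLocus],
    genome: Mapping[str, str],
    annotations: Optional[AnnotationSet] = None,
    length_range: tuple[int, int] = CANDIDATE_LENGTH_RANGE,
    strand_fraction: float = DEFAULT_STRAND_FRACTION,
    localization: float = DEFAULT_LOCALIZATION,
    entropy_min: float = ENTROPY_MIN_BITS,
    dinucleotide_max: float = DINUCLEOTIDE_MAX_FRACTION,
) -> list[CandidateLocus]:
    """Select PILE loci compatible with precise small-ncRNA processing.

    Filters: dominant read length within ``length_range`` (default 19-29
    nt), strand specificity, 5'-end localization, consensus sequence
    complexity (Shannon entropy >= 1.5 bits/nt and no dinucleotide
    covering >= 60% of the sequence), and a degradation proxy rejecting
    loci lying fully inside an abundant structural RNA (rRNA) without a
    localized 5'-end mode.  Each retained locus is typed by annotation
    overlap: tRNA-associated > known-ncRNA > intergenic-novel.
    """
    out: list[CandidateLocus] = []
    for locus in loci:
        if locus.chrom not in genome:
            raise ValueError(
                f"genome sequence unavailable for {locus.chrom} (complexity test)"
            )
        seq = genome[locus.chrom][locus.start : locus.end]
        filters = {
            "length": length_range[0] <= locus.dominant_length <= length_range[1],
            "strand": locus.strand_fraction >= strand_fraction,
            "localization": locus.localization >= localization,
            "complexity": (
                shannon_entropy(seq) >= entropy_min
                and _max_dinucleotide_fraction(seq) < dinucleotide_max
            ),
            "degradation": True,
        }
        ctype = "intergenic-novel"
        if annotations is not None:
            if annotations.query("trnas", locus.chrom, locus.start, locus.end):
                ctype = "tRNA-associated"
            else:
                overlapping_nc = annotations.query(
                    "ncrnas", locus.chrom, locus.start, locus.end
                )
                if overlapping_nc:
                    ctype = "known-ncRNA"
                    # degradation proxy: fully inside an rRNA-like structural
                    # RNA and no localized 5'-end mode
                    for nc in overlapping_nc:
                        ntype = str(nc.attrs.get("type", "")).lower()
                        if (
                            "rrna" in ntype
                            and nc.start <= locus.start
                            and locus.end <= nc.end
                            and locus.localization < localization
                        ):
                            filters["degradation"] = False
        if all(filters.values()):
            out.append(
                CandidateLocus(
                    locus=locus,
                    passed_filters=filters,
                    candidate_type=ctype,
                    libraries=set(locus.libraries),
                )
            )
    return out


def merge_across_libraries(
    candidates_per_library: Mapping[str, Sequence[CandidateLocus]],
) -> list[CandidateLocus]:
    """Union of candidate intervals across libraries.

    Overlapping candidate intervals from any libraries are merged into a
    single locus spanning their union; the merged record lists supporting
    libraries and ``support`` = number of libraries that detected it.
    Idempotent and independent of library order.
    """
    pool: list[tuple[str, int, int, str, CandidateLocus]] = []
    for lib in candidates_per_library:
        for c in candidates_per_library[lib]:
            pool.append((c.chrom, c.start, c.end, lib, c))
    pool.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: list[CandidateLocus] = []
    group: list[tuple[str, int, int, str, CandidateLocus]] = []

    def _flush(group):
        if not group:
            return
        chrom = group[0][0]
        start = min(g[1] for g in group)
        end = max(g[2] for g in group)
        libs = sorted({g[3] for g in group})
        # representative member: most reads
        rep = max((g[4] for g in group), key=lambda c: c.locus.read_count)
        all_reads = []
        for g in group:
            all_reads.extend(g[4].locus.reads)
        merged.append(
            CandidateLocus(
                locus=SrnaLocus(chrom=chrom, start=start, end=end, reads=all_reads),
                passed_filters=dict(rep.passed_filters),
                candidate_type=rep.candidate_type,
                libraries=set(libs),
                support=len(libs),
            )
        )

    cur_chrom, cur_end = None, -math.inf
    for item in pool:
        chrom, start, end = item[0], item[1], item[2]
        if group and (chrom != cur_chrom or start >= cur_end):
            _flush(group)
            group = []
            cur_end = -math.inf
        group.append(item)
        cur_chrom = chrom
        cur_end = max(cur_end, end)
    _flush(group)
    return merged


def loci_to_bed(loci: Sequence[SrnaLocus], path, classes: Optional[Sequence[str]] = None) -> None:
    """Write loci as BED6+ (class, read_count, strand_fraction, dominant_length, libraries)."""
    with open(path, "w") as fh:
        for i, locus in enumerate(loci):
            cls = classes[i] if classes else classify_distribution(locus)
            fh.write(
                "\t".join(
                    [
                        locus.chrom, str(locus.start), str(locus.end),
                        f"locus_{i+1}", str(locus.read_count), locus.strand,
                        cls, f"{locus.strand_fraction:.3f}",
                        str(locus.dominant_length),
                        ",".join(sorted(locus.libraries)) or ".",
                    ]
                )
                + "\n"
            )
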