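"""Alignment and annotation IO, and weighted coverage tracks.

All internal coordinates are 0-based half-open (BED convention). GFF3 input
(1-based inclusive) is shifted on read and shifted back on write.

Small-RNA alignments are accepted either as BAM (multiplicity from the NH
tag when present) or as a BED dialect with columns::

    chrom  start  end  name  score  strand  [multiplicity]

where the ``name`` column carries the read sequence when it is available
("." otherwise) — sequence is needed downstream for CCA detection and 5'
nucleotide composition — and the optional 7th column is the number of
genomic matches of the read (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "AlignedRead",
    "CoverageTrack",
    "Feature",
    "TrnaGene",
    "AnnotationSet",
    "load_genome",
    "load_alignments",
    "load_annotations",
    "compute_coverage",
    "write_reads_bed",
    "write_fasta",
]

#: default size-selected fraction, nt
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 36

_NUC = set("ACGTUNacgtun")


@dataclass
class AlignedRead:
    """One aligned small-RNA fragment.

    ``multiplicity`` is the number of genomic locations the read matches;
    its reciprocal is the read's contribution ``weight`` to reweighted
    coverage, so ``weight * multiplicity == 1`` always holds.
    """

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'
    sequence: Optional[str] = None
    multiplicity: int = 1
    library: str = ""
    out_of_range: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"read end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def weight(self) -> float:
        return 1.0 / self.multiplicity

    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (strand-aware, 0-based)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class CoverageTrack:
    """Per-position weighted read-count vector for one chromosome."""

    chrom: str
    values: np.ndarray
    mode: str = "reweighted"  # 'unique' or 'reweighted'
    strand: str = "both"  # '+', '-', 'both'

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class Feature:
    """A stranded/unstranded annotated interval with free-form attributes."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    attrs: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


# canonical tRNA arm names, 5'→3'
TRNA_ARMS = ("acceptor_stem", "d_loop", "anticodon_loop", "t_loop")


@dataclass
class TrnaGene(Feature):
    """tRNA gene with arm sub-coordinates relative to the gene 5' end.

    ``arms`` maps arm name → (rel_start, rel_end), half-open, in mature
    (strand-oriented) coordinates.  The mature 3' terminus is at
    ``length`` (includes a genome-templated CCA when annotated so).
    """

    isotype: str = ""
    anticodon: str = ""
    arms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [a for a in TRNA_ARMS if a not in self.arms]
        if missing:
            raise ValueError(
                f"tRNA {self.name or self.chrom} lacks arm sub-coordinates: "
                f"{', '.join(missing)} (tRF classification impossible)"
            )


class AnnotationSet:
    """Indexed annotation categories for fast interval-overlap queries.

    Categories: ``genes``, ``repeats``, ``trnas``, ``ncrnas`` (non-tRNA
    structured RNAs), ``methylation`` (probes with a binary call in
    ``attrs['methylated']``).
    """

    CATEGORIES = ("genes", "repeats", "trnas", "ncrnas", "methylation")

    def __init__(
        self,
        genes: Sequence[Feature] = (),
        repeats: Sequence[Feature] = (),
        trnas: Sequence[TrnaGene] = (),
        ncrnas: Sequence[Feature] = (),
        methylation: Sequence[Feature] = (),
        chrom_sizes: Optional[Mapping[str, int]] = None,
    ) -> None:
        self.genes = list(genes)
        self.repeats = list(repeats)
        self.trnas = list(trnas)
        self.ncrnas = list(ncrnas)
        self.methylation = list(methylation)
        self.chrom_sizes = dict(chrom_sizes or {})
        if self.chrom_sizes:
            for cat in self.CATEGORIES:
                for f in getattr(self, cat):
                    size = self.chrom_sizes.get(f.chrom)
                    if size is not None and (f.start < 0 or f.end > size):
                        raise ValueError(
                            f"{cat} feature {f.name or ''} {f.chrom}:{f.start}-{f.end} "
                            f"outside chromosome bounds (size {size})"
                        )
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        for cat in self.CATEGORIES:
            trees: dict[str, IntervalTree] = {}
            for f in getattr(self, cat):
                trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
            self._trees[cat] = trees

    def query(self, category: str, chrom: str, start: int, end: int) -> list:
        """Features of ``category`` overlapping [start, end) by >= 1 bp."""
        trees = self._trees[category]
        if chrom not in trees:
            return []
        return [iv.data for iv in sorted(trees[chrom].overlap(start, end))]


# ---------------------------------------------------------------------------
# genome / alignments


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a {chrom: sequence} dict (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _parse_bed_alignment(line: str, lineno: int, library: str) -> AlignedRead:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 6:
        raise ValueError(
            f"malformed alignment BED record at line {lineno}: "
            f"expected >= 6 columns, got {len(fields)}"
        )
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"malformed alignment BED record at line {lineno}: {exc}")
    name = fields[3]
    seq = name.upper() if name != "." and set(name) <= _NUC else None
    strand = fields[5]
    mult = 1
    if len(fields) >= 7 and fields[6] not in (".", ""):
        try:
            mult = int(fields[6])
        except ValueError:
            raise ValueError(
                f"malformed multiplicity column at line {lineno}: {fields[6]!r}"
            )
    return AlignedRead(
        chrom=fields[0], start=start, end=end, strand=strand,
        sequence=seq, multiplicity=mult, library=library,
    )


def load_alignments(
    path: str | Path,
    library: str = "",
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[AlignedRead]:
    """Load aligned reads from BAM/SAM or the alignment BED dialect.

    Reads outside [min_len, max_len] are returned with ``out_of_range``
    set (flagged, not dropped); downstream stages exclude them by default.
    BAM multiplicity comes from the NH tag when present.
    """
    path = Path(path)
    reads: list[AlignedRead] = []
    if path.suffix.lower() in (".bam", ".sam", ".cram"):
        import pysam

        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.is_unmapped:
                    continue
                mult = aln.get_tag("NH") if aln.has_tag("NH") else 1
                seq = aln.query_sequence
                reads.append(
                    AlignedRead(
                        chrom=aln.reference_name,
                        start=aln.reference_start,
                        end=aln.reference_end,
                        strand="-" if aln.is_reverse else "+",
                        sequence=seq.upper() if seq else None,
                        multiplicity=int(mult),
                        library=library,
                    )
                )
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                reads.append(_parse_bed_alignment(line, lineno, library))
    if chrom_sizes is not None:
        known = set(chrom_sizes)
        for r in reads:
            if r.chrom not in known:
                raise ValueError(
                    f"unknown chromosome {r.chrom!r}; genome has: "
                    + ", ".join(sorted(known))
                )
    for r in reads:
        if not (min_len <= r.length <= max_len):
            r.out_of_range = True
    return reads


def in_range(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Reads within the configured length bounds (default downstream set)."""
    return [r for r in reads if not r.out_of_range]


def compute_coverage(
    reads: Iterable[AlignedRead],
    chrom_sizes: Mapping[str, int],
    mode: str = "reweighted",
    strand_mode: str = "both",
) -> dict[str, CoverageTrack]:
    """Build per-chromosome coverage.

    ``mode='unique'`` counts only multiplicity-1 reads with weight 1;
    ``mode='reweighted'`` adds 1/multiplicity per covered position.
    ``strand_mode`` in {'both', '+', '-'} restricts contributing reads.
    """
    if mode not in ("unique", "reweighted"):
        raise ValueError(f"mode must be 'unique' or 'reweighted', got {mode!r}")
    if strand_mode not in ("both", "+", "-"):
        raise ValueError(f"strand_mode must be 'both', '+' or '-', got {strand_mode!r}")
    values = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    for r in reads:
        if strand_mode != "both" and r.strand != strand_mode:
            continue
        if mode == "unique":
            if r.multiplicity != 1:
                continue
            w = 1.0
        else:
            w = r.weight
        v = values.get(r.chrom)
        if v is None:
            raise ValueError(
                f"unknown chromosome {r.chrom!r}; genome has: "
                + ", ".join(sorted(chrom_sizes))
            )
        v[max(r.start, 0) : min(r.end, len(v))] += w
    return {
        c: CoverageTrack(chrom=c, values=v, mode=mode, strand=strand_mode)
        for c, v in values.items()
    }


# ---------------------------------------------------------------------------
# annotations


def _parse_gff_attrs(col: str) -> dict:
    attrs = {}
    for part in col.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def load_gff(path: str | Path) -> list[Feature]:
    """Parse a GFF3 file into Features (coordinates shifted to 0-based)."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"malformed GFF record at line {lineno}")
            attrs = _parse_gff_attrs(cols[8]) if len(cols) > 8 else {}
            attrs["type"] = cols[2]
            attrs["source"] = cols[1]
            feats.append(
                Feature(
                    chrom=cols[0],
                    start=int(cols[3]) - 1,  # GFF 1-based inclusive
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else ".",
                    name=attrs.get("ID", attrs.get("Name", "")),
                    attrs=attrs,
                )
            )
    return feats


def write_gff(features: Sequence[Feature], path: str | Path) -> None:
    """Write Features back out as GFF3 (0-based internal → 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = {k: v for k, v in f.attrs.items() if k not in ("type", "source")}
            if f.name and "ID" not in attrs:
                attrs["ID"] = f.name
            col9 = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        str(f.attrs.get("source", "srnascape")),
                        str(f.attrs.get("type", "region")),
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand if f.strand in "+-" else ".",
                        ".",
                        col9,
                    ]
                )
                + "\n"
            )


def load_bed_features(path: str | Path) -> list[Feature]:
    """Plain BED3/BED6 → Features."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise ValueError(f"malformed BED record at line {lineno}")
            feats.append(
                Feature(
                    chrom=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    name=cols[3] if len(cols) > 3 else "",
                    strand=cols[5] if len(cols) > 5 and cols[5] in "+-" else ".",
                )
            )
    return feats


def load_methylation_bed(path: str | Path) -> list[Feature]:
    """Methylation probes: BED with a 0/1 call column (column 5 or last)."""
    probes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 4:
                raise ValueError(
                    f"methylation BED needs a call column, line {lineno}"
                )
            call_col = cols[4] if len(cols) > 4 else cols[3]
            if call_col not in ("0", "1"):
                raise ValueError(
                    f"methylation call must be 0 or 1, got {call_col!r} at line {lineno}"
                )
            probes.append(
                Feature(
                    chrom=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    name=cols[3] if len(cols) > 4 else "",
                    attrs={"methylated": int(call_col)},
                )
            )
    return probes


#: required columns of the tRNA arm-model table
TRNA_TSV_COLUMNS = [
    "chrom", "start", "end", "strand", "name", "isotype", "anticodon",
    "acceptor_stem_start", "acceptor_stem_end",
    "d_loop_start", "d_loop_end",
    "anticodon_loop_start", "anticodon_loop_end",
    "t_loop_start", "t_loop_end",
]


def load_trna_table(path: str | Path) -> list[TrnaGene]:
    """tRNA gene table (TSV) with arm sub-coordinates relative to 5' end."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRNA_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            "tRNA table lacks arm sub-coordinate columns: "
            + ", ".join(missing)
            + " (tRF classification impossible)"
        )
    genes = []
    for _, row in df.iterrows():
        arms = {
            arm: (int(row[f"{arm}_start"]), int(row[f"{arm}_end"]))
            for arm in TRNA_ARMS
        }
        genes.append(
            TrnaGene(
                chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
                strand=row["strand"], name=row["name"],
                isotype=row["isotype"], anticodon=row["anticodon"], arms=arms,
            )
        )
    return genes


def write_trna_table(trnas: Sequence[TrnaGene], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for t in trnas:
        row = {
            "chrom": t.chrom, "start": t.start, "end": t.end, "strand": t.strand,
            "name": t.name, "isotype": t.isotype, "anticodon": t.anticodon,
        }
        for arm in TRNA_ARMS:
            row[f"{arm}_start"], row[f"{arm}_end"] = t.arms[arm]
        rows.append(row)
    pd.DataFrame(rows, columns=TRNA_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def load_annotations(
    genome: Mapping[str, str] | str | Path,
    gff_path: Optional[str | Path] = None,
    methylation_path: Optional[str | Path] = None,
    trna_path: Optional[str | Path] = None,
) -> AnnotationSet:
    """Assemble an AnnotationSet from a genome plus annotation files.

    GFF3 feature types map to categories: gene/mRNA/CDS → genes;
    repeat/transposable_element/TE → repeats; *RNA types → ncrnas
    (tRNAs come from the dedicated arm-model TSV).
    """
    if not isinstance(genome, Mapping):
        genome = load_genome(genome)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    genes, repeats, ncrnas = [], [], []
    if gff_path:
        for f in load_gff(gff_path):
            ftype = f.attrs.get("type", "").lower()
            if ftype in ("gene", "mrna", "cds", "exon"):
                genes.append(f)
            elif "repeat" in ftype or "transposable" in ftype or ftype == "te":
                repeats.append(f)
            elif ftype.endswith("rna") or ftype in ("ncrna", "snorna", "snrna", "rrna"):
                ncrnas.append(f)
    methylation = load_methylation_bed(methylation_path) if methylation_path else []
    trnas = load_trna_table(trna_path) if trna_path else []
    return AnnotationSet(
        genes=genes, repeats=repeats, trnas=trnas, ncrnas=ncrnas,
        methylation=methylation, chrom_sizes=chrom_sizes,
    )


# ---------------------------------------------------------------------------
# writers


def write_reads_bed(reads: Sequence[AlignedRead], path: str | Path) -> None:
    """Write reads in the alignment BED dialect (name column = sequence)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                "\t".join(
                    [
                        r.chrom, str(r.start), str(r.end),
                        r.sequence or ".", "0", r.strand, str(r.multiplicity),
                    ]
                )
                + "\n"
            )


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
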