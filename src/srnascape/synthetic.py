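"""Synthetic small-RNA study generator with machine-readable truth tables.

Generates a toy genome plus annotations, a methylation probe track, an
expression table and per-library aligned-read sets that reproduce the
statistical structure the analysis stages assume:

* strand-specific, sequence-specific *piles* of identical reads
  (processed-sRNA signature), at depths of order 10^3;
* one intergenic *plateau* locus built from two overlapping fragment
  lengths (24 and 25 nt) sharing near-identical 5' ends;
* one U2-snRNA-like gene with a dominant 3'-end pile and a ~20x weaker
  5'-end pile (default depths 2600 and 120, preserving the ~22:1 ratio
  seen in real data);
* tRNA genes emitting tRFs of every class with truth labels, with CCA
  both genome-templated and read-appended;
* transposable elements covered on both strands by 25-30 nt reads with a
  ~60% 5'-U bias; methylated TEs get high coverage and low expression,
  unmethylated TEs the converse, so coverage/methylation/expression
  associations are planted by construction;
* one highly-methylated region carrying regularly spaced read piles
  (default period 180 nt) for the periodicity scan;
* a uniform degradation background with geometric read lengths, plus an
  rRNA-hosted degradation smear to exercise the degradation filter.

Everything is a pure function of the seed: identical seeds give
byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_coverage import (
    AlignedRead,
    AnnotationSet,
    Feature,
    TrnaGene,
    write_fasta,
    write_gff,
    write_reads_bed,
    write_trna_table,
)

__all__ = ["SyntheticConfig", "Bundle", "generate", "truth_compare",
           "sample_trf_reads", "sample_te_reads", "periodic_coverage_reads",
           "make_hairpin_genome"]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults mirror the structure of
    a diatom small-RNA experiment at desk scale."""

    seed: int = 17
    chrom_lengths: tuple[int, ...] = (60_000, 40_000)
    gc: float = 0.48
    libraries: tuple[str, ...] = ("NL",)

    # pile loci (processed-sRNA signature)
    n_pile_loci: int = 12
    pile_depth: int = 1200
    pile_lengths: tuple[int, ...] = (21, 24, 25, 22)

    # intergenic plateau locus: two overlapping fragment lengths
    plateau_lengths: tuple[int, int] = (24, 25)
    plateau_depth: int = 2500  # per fragment length
    plateau_offset: int = 1  # 5'-end shift between the two stacks, nt

    # U2-like locus
    u2_gene_length: int = 226
    u2_three_prime_depth: int = 2600
    u2_five_prime_depth: int = 120
    u2_read_length: int = 25

    # tRNA genes / tRFs
    n_trnas: int = 6
    trf_class_depths: dict = field(
        default_factory=lambda: {
            "3p_short": 600,
            "dloop_anticodon": 150,
            "3p_long": 120,
            "5p_long": 80,
            "half_tRNA": 50,
        }
    )

    # TEs
    n_te: int = 8
    te_length_range: tuple[int, int] = (900, 3000)
    te_read_length_range: tuple[int, int] = (25, 30)
    te_first_u_prob: float = 0.6
    te_high_rpkm_depth_per_kb: int = 700  # methylated/silenced TEs
    te_low_rpkm_depth_per_kb: int = 0  # expressed TEs (background only)
    te_families: tuple[str, ...] = ("Copia", "PiggyBac")
    multimapper_fraction: float = 0.1  # duplicated Copia pair reads
    #: coverage on methylated TEs is clustered into regularly spaced read
    #: piles (as observed on silenced LTR retrotransposons) with this
    #: spacing, plus a uniform component
    te_pile_period: int = 190
    te_uniform_fraction: float = 0.3

    # HMR periodic region
    hmr_span: int = 5400
    hmr_period: int = 180
    hmr_pile_width: int = 25
    hmr_pile_depth: int = 60
    hmr_jitter: int = 2

    # genes (for expression percentile / gene-methylation analyses)
    n_genes: int = 24
    gene_length: int = 1200

    # degradation background
    background_rate_per_nt: float = 5e-4
    probe_spacing: int = 60


@dataclass
class Bundle:
    """In-memory synthetic study: genome, annotations, reads and truth."""

    config: SyntheticConfig
    genome: dict[str, str]
    annotations: AnnotationSet
    reads: dict[str, list[AlignedRead]]
    expression: pd.DataFrame
    truth: dict[str, pd.DataFrame]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def all_reads(self) -> list[AlignedRead]:
        out = []
        for lib in sorted(self.reads):
            out.extend(self.reads[lib])
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle as plain-text files (FASTA/GFF3/BED/TSV)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome"] = outdir / "genome.fa"
        write_fasta(self.genome, paths["genome"])
        feats = (
            self.annotations.genes + self.annotations.repeats + self.annotations.ncrnas
        )
        paths["annotations"] = outdir / "annotations.gff3"
        write_gff(feats, paths["annotations"])
        paths["methylation"] = outdir / "methylation.bed"
        with open(paths["methylation"], "w") as fh:
            for p in self.annotations.methylation:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or 'probe'}\t"
                    f"{int(p.attrs.get('methylated', 0))}\n"
                )
        paths["trnas"] = outdir / "trnas.tsv"
        write_trna_table(self.annotations.trnas, paths["trnas"])
        paths["expression"] = outdir / "expression.tsv"
        self.expression.to_csv(paths["expression"], sep="\t", index=False)
        for lib, reads in self.reads.items():
            p = outdir / f"reads_{lib}.bed"
            write_reads_bed(reads, p)
            paths[f"reads_{lib}"] = p
        for name, df in self.truth.items():
            p = outdir / f"truth_{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[f"truth_{name}"] = p
        return paths


# ---------------------------------------------------------------------------
# helpers


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _read_seq(genome: dict[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    s = genome[chrom][start:end]
    return _revcomp(s) if strand == "-" else s


class _Layout:
    """Sequential feature placement with margins on one chromosome set."""

    def __init__(self, chrom_lengths: Sequence[int], margin: int = 400):
        self.lengths = list(chrom_lengths)
        self.margin = margin
        self.cursor = [margin] * len(self.lengths)

    def place(self, length: int) -> tuple[int, int]:
        """Return (chrom_index, start) for a feature of ``length`` nt."""
        for i, clen in enumerate(self.lengths):
            if self.cursor[i] + length + self.margin <= clen:
                start = self.cursor[i]
                self.cursor[i] += length + self.margin
                return i, start
        raise ValueError(
            f"infeasible placement: feature of {length} nt exceeds remaining genome"
        )


# ---------------------------------------------------------------------------
# feature-level read samplers (exposed for targeted tests)


def sample_trf_reads(
    trna: TrnaGene,
    genome: dict[str, str],
    class_depths: dict[str, int],
    rng: np.random.Generator,
    library: str = "NL",
    cca_templated: bool = True,
) -> tuple[list[AlignedRead], list[str]]:
    """Reads for each tRF class of one tRNA, with truth labels.

    Lengths are drawn inside each class's window: 3p_short and
    dloop_anticodon 18-21 nt, 3p_long and 5p_long 31-35 nt; half_tRNA
    spans the 5' end through the anticodon loop.  3'-anchored fragments
    carry CCA: templated from the genome when ``cca_templated``, else
    appended onto the read sequence only.
    """
    reads: list[AlignedRead] = []
    labels: list[str] = []
    tlen = trna.length
    ac0, ac1 = trna.arms["anticodon_loop"]
    d0, d1 = trna.arms["d_loop"]

    def rel_to_genomic(rel_start: int, rel_end: int) -> tuple[int, int]:
        if trna.strand == "-":
            return trna.end - rel_end, trna.end - rel_start
        return trna.start + rel_start, trna.start + rel_end

    for cls in sorted(class_depths):
        depth = class_depths[cls]
        for _ in range(depth):
            if cls == "3p_short":
                length = int(rng.integers(18, 22))
                rel = (tlen - length, tlen)
            elif cls == "3p_long":
                length = int(rng.integers(31, 36))
                rel = (tlen - length, tlen)
            elif cls == "5p_long":
                # stop short of the anticodon, where the half-tRNA class
                # begins
                mid = (ac0 + ac1) // 2
                length = int(rng.integers(31, min(36, mid)))
                rel = (0, length)
            elif cls == "half_tRNA":
                # 5' end through the anticodon (distal half of the loop),
                # capped at the 36-nt size-selection limit
                mid = (ac0 + ac1) // 2
                rel = (0, int(rng.integers(mid, min(ac1, 36) + 1)))
            elif cls == "dloop_anticodon":
                length = int(rng.integers(18, 22))
                loop = (d0, d1) if rng.random() < 0.5 else (ac0, ac1)
                lo = max(0, loop[0] - 2)
                hi = min(tlen - length, loop[1] - 2)
                start = int(rng.integers(lo, max(lo + 1, hi)))
                rel = (start, start + length)
            else:
                raise ValueError(f"unknown tRF class {cls!r}")
            g0, g1 = rel_to_genomic(*rel)
            seq = _read_seq(genome, trna.chrom, g0, g1, trna.strand)
            if cls in ("3p_short", "3p_long") and not cca_templated:
                seq = seq[:-3] + "CCA"  # post-transcriptionally added
            reads.append(
                AlignedRead(
                    chrom=trna.chrom, start=g0, end=g1, strand=trna.strand,
                    sequence=seq, multiplicity=1, library=library,
                )
            )
            labels.append(cls)
    return reads, labels


def periodic_coverage_reads(
    chrom: str,
    region_start: int,
    span: int,
    genome: dict[str, str],
    rng: np.random.Generator,
    period: int = 180,
    pile_width: int = 25,
    pile_depth: int = 60,
    jitter: int = 2,
    library: str = "NL",
    first_u_prob: float = 0.6,
) -> list[AlignedRead]:
    """Regularly spaced both-strand read piles emulating HMR coverage.

    The reads are the same 25-30 nt TE-associated population elsewhere in
    the model, so they carry the same 5'-U composition bias.
    """
    reads = []
    n_piles = span // period
    for k in range(n_piles):
        center = region_start + k * period + int(rng.integers(-jitter, jitter + 1))
        start = max(0, center)
        end = min(len(genome[chrom]), start + pile_width)
        if end - start < pile_width:
            continue
        for _ in range(pile_depth):
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _read_seq(genome, chrom, start, end, strand)
            if rng.random() < first_u_prob:
                seq = "T" + seq[1:]
            else:
                seq = str(rng.choice(["A", "C", "G"])) + seq[1:]
            reads.append(
                AlignedRead(
                    chrom=chrom, start=start, end=end, strand=strand,
                    sequence=seq, multiplicity=1, library=library,
                )
            )
    return reads


def sample_te_reads(
    te: Feature,
    genome: dict[str, str],
    rng: np.random.Generator,
    n_reads: int,
    length_range: tuple[int, int],
    first_u_prob: float,
    library: str,
    multiplicity: int = 1,
    pile_period: int = 0,
    uniform_fraction: float = 1.0,
) -> list[AlignedRead]:
    """Both-strand 25-30 nt reads over a TE with a 5'-U composition bias.

    With ``pile_period > 0``, a ``1 - uniform_fraction`` share of the reads
    is clustered into regularly spaced piles across the element (the
    coverage shape seen on silenced LTR retrotransposons); the rest is
    uniform over the element.
    """
    reads = []
    lo, hi = length_range
    pile_starts: list[int] = []
    if pile_period > 0:
        pile_starts = [
            te.start + k * pile_period + int(rng.integers(-2, 3))
            for k in range(max(1, te.length // pile_period))
        ]
    for i in range(n_reads):
        length = int(rng.integers(lo, hi + 1))
        if pile_starts and rng.random() >= uniform_fraction:
            start = pile_starts[int(rng.integers(0, len(pile_starts)))]
            start = min(max(start, te.start), te.end - length)
        else:
            start = int(rng.integers(te.start, max(te.start + 1, te.end - length)))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _read_seq(genome, te.chrom, start, end, strand)
        # plant the 5'-end composition bias on the read sequence
        if rng.random() < first_u_prob:
            first = "T"
        else:
            first = str(rng.choice(["A", "C", "G"]))
        seq = first + seq[1:]
        reads.append(
            AlignedRead(
                chrom=te.chrom, start=start, end=end, strand=strand,
                sequence=seq, multiplicity=multiplicity, library=library,
            )
        )
    return reads


def make_hairpin_genome(
    rng: np.random.Generator,
    arm_length: int = 30,
    loop_length: int = 8,
    genome_length: int = 30_000,
    gc: float = 0.48,
) -> tuple[dict[str, str], tuple[str, int, int]]:
    """A random genome with one planted perfect inverted repeat.

    Returns (genome, (chrom, start, end)) where [start, end) is the
    planted hairpin (arm + loop + reverse-complement arm).
    """
    seq = _random_sequence(rng, genome_length, gc)
    arm = _random_sequence(rng, arm_length, 0.6)
    loop = _random_sequence(rng, loop_length, gc)
    hairpin = arm + loop + _revcomp(arm)
    pos = genome_length // 2
    seq = seq[:pos] + hairpin + seq[pos + len(hairpin):]
    return {"chrH": seq}, ("chrH", pos, pos + len(hairpin))


# ---------------------------------------------------------------------------
# main generator


def generate(config: Optional[SyntheticConfig] = None) -> Bundle:
    """Build the full synthetic bundle from a config (seed-deterministic)."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i+1}" for i in range(len(cfg.chrom_lengths))]
    genome = {
        c: _random_sequence(rng, n, cfg.gc)
        for c, n in zip(chroms, cfg.chrom_lengths)
    }
    layout = _Layout(cfg.chrom_lengths)
    libraries = list(cfg.libraries)
    reads: dict[str, list[AlignedRead]] = {lib: [] for lib in libraries}
    truth_loci: list[dict] = []
    truth_trf: list[dict] = []
    truth_te: list[dict] = []
    truth_period: list[dict] = []
    genes: list[Feature] = []
    repeats: list[Feature] = []
    ncrnas: list[Feature] = []
    trnas: list[TrnaGene] = []
    probes: list[Feature] = []
    expr_rows: list[dict] = []

    def _embed(chrom: str, start: int, sub: str) -> None:
        genome[chrom] = genome[chrom][:start] + sub + genome[chrom][start + len(sub):]

    # --- pile loci ---------------------------------------------------------
    for i in range(cfg.n_pile_loci):
        length = cfg.pile_lengths[i % len(cfg.pile_lengths)]
        ci, start = layout.place(length)
        chrom = chroms[ci]
        strand = "+" if i % 2 == 0 else "-"
        end = start + length
        seq = _read_seq(genome, chrom, start, end, strand)
        for lib in libraries:
            for _ in range(cfg.pile_depth):
                reads[lib].append(
                    AlignedRead(chrom=chrom, start=start, end=end, strand=strand,
                                sequence=seq, multiplicity=1, library=lib)
                )
        truth_loci.append(
            {"chrom": chrom, "start": start, "end": end, "kind": "pile",
             "distribution_class": "PILE", "dominant_length": length,
             "strand": strand,
             "depth": cfg.pile_depth * len(libraries)}
        )

    # --- intergenic plateau locus -----------------------------------------
    l24, l25 = cfg.plateau_lengths
    span = max(l24, l25) + cfg.plateau_offset
    ci, start = layout.place(span)
    chrom = chroms[ci]
    for lib in libraries:
        for _ in range(cfg.plateau_depth):
            s = start
            e = s + l24
            reads[lib].append(
                AlignedRead(chrom=chrom, start=s, end=e, strand="+",
                            sequence=_read_seq(genome, chrom, s, e, "+"),
                            multiplicity=1, library=lib)
            )
            s2 = start + cfg.plateau_offset
            e2 = s2 + l25
            reads[lib].append(
                AlignedRead(chrom=chrom, start=s2, end=e2, strand="+",
                            sequence=_read_seq(genome, chrom, s2, e2, "+"),
                            multiplicity=1, library=lib)
            )
    truth_loci.append(
        {"chrom": chrom, "start": start, "end": start + span, "kind": "plateau",
         "distribution_class": "PILE", "dominant_length": min(l24, l25),
         "strand": "+", "depth": 2 * cfg.plateau_depth * len(libraries)}
    )

    # --- U2-like locus ------------------------------------------------------
    ci, start = layout.place(cfg.u2_gene_length)
    chrom = chroms[ci]
    u2 = Feature(chrom=chrom, start=start, end=start + cfg.u2_gene_length,
                 strand="+", name="U2_snRNA", attrs={"type": "snRNA"})
    ncrnas.append(u2)
    rl = cfg.u2_read_length
    three_start = u2.end - rl
    five_start = u2.start
    for lib in libraries:
        for _ in range(cfg.u2_three_prime_depth):
            reads[lib].append(
                AlignedRead(chrom=chrom, start=three_start, end=three_start + rl,
                            strand="+",
                            sequence=_read_seq(genome, chrom, three_start, three_start + rl, "+"),
                            multiplicity=1, library=lib)
            )
        for _ in range(cfg.u2_five_prime_depth):
            reads[lib].append(
                AlignedRead(chrom=chrom, start=five_start, end=five_start + 21,
                            strand="+",
                            sequence=_read_seq(genome, chrom, five_start, five_start + 21, "+"),
                            multiplicity=1, library=lib)
            )
    truth_loci.append(
        {"chrom": chrom, "start": three_start, "end": three_start + rl,
         "kind": "u2_3p", "distribution_class": "PILE", "dominant_length": rl,
         "strand": "+", "depth": cfg.u2_three_prime_depth * len(libraries)}
    )
    truth_loci.append(
        {"chrom": chrom, "start": five_start, "end": five_start + 21,
         "kind": "u2_5p", "distribution_class": "PILE", "dominant_length": 21,
         "strand": "+", "depth": cfg.u2_five_prime_depth * len(libraries)}
    )

    # --- one rRNA with unlocalized degradation smear (filter exercise) -----
    ci, start = layout.place(600)
    chrom = chroms[ci]
    rrna = Feature(chrom=chrom, start=start, end=start + 600, strand="+",
                   name="rRNA_5S_like", attrs={"type": "rRNA"})
    ncrnas.append(rrna)
    for lib in libraries:
        for _ in range(200):
            length = int(rng.integers(18, 31))
            s = int(rng.integers(rrna.start, rrna.end - length))
            reads[lib].append(
                AlignedRead(chrom=chrom, start=s, end=s + length, strand="+",
                            sequence=_read_seq(genome, chrom, s, s + length, "+"),
                            multiplicity=1, library=lib)
            )
    truth_loci.append(
        {"chrom": chrom, "start": rrna.start, "end": rrna.end,
         "kind": "degradation", "distribution_class": "DISTRIBUTED",
         "dominant_length": -1, "strand": "+", "depth": 200 * len(libraries)}
    )

    # --- tRNA genes ---------------------------------------------------------
    # canonical 76-nt mature layout (rel coords): acceptor stem 0-7,
    # D loop 14-21, anticodon loop 30-39, T loop 53-61, CCA at 73-76
    arms = {"acceptor_stem": (0, 7), "d_loop": (14, 21),
            "anticodon_loop": (30, 39), "t_loop": (53, 61)}
    isotypes = ["Glu", "Asp", "Pro", "Gly", "Lys", "His", "Ser", "Leu"]
    anticodons = ["GAG", "CAG", "CCT", "GCC", "AAG", "GTG", "TCA", "TAG"]
    for i in range(cfg.n_trnas):
        tlen = 76
        ci, start = layout.place(tlen)
        chrom = chroms[ci]
        strand = "+" if i % 2 == 0 else "-"
        cca_templated = i % 2 == 0
        body = _random_sequence(rng, tlen - 3, 0.5)
        gene_seq = body + ("CCA" if cca_templated else _random_sequence(rng, 3, 0.5))
        _embed(chrom, start, gene_seq if strand == "+" else _revcomp(gene_seq))
        trna = TrnaGene(
            chrom=chrom, start=start, end=start + tlen, strand=strand,
            name=f"tRNA_{isotypes[i % 8]}_{anticodons[i % 8]}_{i+1}",
            isotype=isotypes[i % 8], anticodon=anticodons[i % 8], arms=dict(arms),
        )
        trnas.append(trna)
        for lib in libraries:
            t_reads, t_labels = sample_trf_reads(
                trna, genome, cfg.trf_class_depths, rng, library=lib,
                cca_templated=cca_templated,
            )
            reads[lib].extend(t_reads)
            for r, lab in zip(t_reads, t_labels):
                truth_trf.append(
                    {"chrom": r.chrom, "start": r.start, "end": r.end,
                     "strand": r.strand, "trna": trna.name, "trf_class": lab,
                     "cca": "present" if lab in ("3p_short", "3p_long") and
                            (r.sequence or "").endswith("CCA") else
                            ("absent" if lab in ("3p_short", "3p_long") else
                             "not_applicable"),
                     "library": lib}
                )

    # --- TEs ----------------------------------------------------------------
    te_lengths = rng.integers(
        cfg.te_length_range[0], cfg.te_length_range[1] + 1, size=cfg.n_te
    )
    # a duplicated Copia pair for multimapper exercise: same length, same seq
    dup_indices = (0, 1) if cfg.n_te >= 2 else ()
    if dup_indices:
        te_lengths[1] = te_lengths[0]
    te_feats: list[Feature] = []
    for i in range(cfg.n_te):
        length = int(te_lengths[i])
        ci, start = layout.place(length)
        chrom = chroms[ci]
        fam = cfg.te_families[i % len(cfg.te_families)]
        methylated = i % 2 == 0  # alternating methylated/silenced vs expressed
        te = Feature(chrom=chrom, start=start, end=start + length, strand="+",
                     name=f"TE_{fam}_{i+1}",
                     attrs={"type": "transposable_element", "family": fam,
                            "methylated": methylated})
        te_feats.append(te)
        repeats.append(te)
    if dup_indices:
        a, b = te_feats[0], te_feats[1]
        _embed(b.chrom, b.start, genome[a.chrom][a.start:a.end])

    total_te_reads = {}
    for i, te in enumerate(te_feats):
        methylated = te.attrs["methylated"]
        depth_per_kb = (
            cfg.te_high_rpkm_depth_per_kb if methylated else cfg.te_low_rpkm_depth_per_kb
        )
        n_reads = int(round(depth_per_kb * te.length / 1000))
        total_te_reads[te.name] = n_reads
        for lib in libraries:
            n_multi = (
                int(round(cfg.multimapper_fraction * n_reads))
                if i in dup_indices
                else 0
            )
            te_reads = sample_te_reads(
                te, genome, rng, n_reads - n_multi, cfg.te_read_length_range,
                cfg.te_first_u_prob, lib,
                pile_period=cfg.te_pile_period if methylated else 0,
                uniform_fraction=cfg.te_uniform_fraction,
            )
            te_reads += sample_te_reads(
                te, genome, rng, n_multi, cfg.te_read_length_range,
                cfg.te_first_u_prob, lib, multiplicity=2,
            )
            reads[lib].extend(te_reads)
        # methylation probes over the TE
        for p in range(te.start, te.end, cfg.probe_spacing):
            call = 1 if methylated else 0
            if rng.random() < 0.1:  # probe noise
                call = 1 - call
            probes.append(
                Feature(chrom=te.chrom, start=p, end=p + 2,
                        name=f"probe_{te.name}_{p}", attrs={"methylated": call})
            )
        expression = (
            float(rng.uniform(0.0, 0.5)) if methylated else float(rng.uniform(20, 100))
        )
        expr_rows.append(
            {"name": te.name, "kind": "TE", "rnaseq": expression,
             "est_count": int(expression / 5)}
        )
        truth_te.append(
            {"name": te.name, "chrom": te.chrom, "start": te.start, "end": te.end,
             "family": te.attrs["family"], "length": te.length,
             "methylated": int(methylated), "expression": expression,
             "n_reads_per_library": n_reads,
             "expected_high_coverage": int(methylated)}
        )

    # --- HMR periodic region -----------------------------------------------
    ci, start = layout.place(cfg.hmr_span)
    chrom = chroms[ci]
    hmr = Feature(chrom=chrom, start=start, end=start + cfg.hmr_span, strand=".",
                  name="HMR_1", attrs={"type": "transposable_element",
                                       "family": "Copia", "methylated": True})
    repeats.append(hmr)
    for p in range(hmr.start, hmr.end, cfg.probe_spacing):
        probes.append(
            Feature(chrom=chrom, start=p, end=p + 2, name=f"probe_HMR_{p}",
                    attrs={"methylated": 1})
        )
    for lib in libraries:
        reads[lib].extend(
            periodic_coverage_reads(
                chrom, hmr.start, cfg.hmr_span, genome, rng,
                period=cfg.hmr_period, pile_width=cfg.hmr_pile_width,
                pile_depth=cfg.hmr_pile_depth, jitter=cfg.hmr_jitter, library=lib,
            )
        )
    truth_period.append(
        {"chrom": chrom, "start": hmr.start, "end": hmr.end,
         "period": cfg.hmr_period, "n_piles": cfg.hmr_span // cfg.hmr_period}
    )

    # --- genes ---------------------------------------------------------------
    for i in range(cfg.n_genes):
        ci, start = layout.place(cfg.gene_length)
        chrom = chroms[ci]
        gene = Feature(chrom=chrom, start=start, end=start + cfg.gene_length,
                       strand="+" if i % 2 == 0 else "-", name=f"gene_{i+1}",
                       attrs={"type": "gene"})
        genes.append(gene)
        expr_rows.append(
            {"name": gene.name, "kind": "gene",
             "rnaseq": float(rng.gamma(2.0, 20.0)), "est_count": int(rng.integers(0, 40))}
        )

    # --- degradation background ---------------------------------------------
    genome_len = sum(cfg.chrom_lengths)
    n_background = rng.poisson(cfg.background_rate_per_nt * genome_len)
    for _ in range(int(n_background)):
        length = 18 + min(int(rng.geometric(0.25)), 18)
        ci = int(rng.integers(0, len(chroms)))
        chrom = chroms[ci]
        s = int(rng.integers(0, cfg.chrom_lengths[ci] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        lib = libraries[int(rng.integers(0, len(libraries)))]
        reads[lib].append(
            AlignedRead(chrom=chrom, start=s, end=s + length, strand=strand,
                        sequence=_read_seq(genome, chrom, s, s + length, strand),
                        multiplicity=1, library=lib)
        )

    annotations = AnnotationSet(
        genes=genes, repeats=repeats, trnas=trnas, ncrnas=ncrnas,
        methylation=probes, chrom_sizes={c: len(s) for c, s in genome.items()},
    )
    truth = {
        "loci": pd.DataFrame(truth_loci),
        "trf": pd.DataFrame(truth_trf),
        "te": pd.DataFrame(truth_te),
        "period": pd.DataFrame(truth_period),
    }
    expression = pd.DataFrame(expr_rows, columns=["name", "kind", "rnaseq", "est_count"])
    return Bundle(
        config=cfg, genome=genome, annotations=annotations, reads=reads,
        expression=expression, truth=truth,
    )


# ---------------------------------------------------------------------------
# recovery scoring


def _interval_match(chrom, start, end, frame: pd.DataFrame) -> bool:
    hit = frame[
        (frame["chrom"] == chrom) & (frame["start"] < end) & (start < frame["end"])
    ]
    return len(hit) > 0


def truth_compare(
    detected_loci: Sequence,
    truth_loci: pd.DataFrame,
    detected_classes: Optional[Sequence[str]] = None,
    kind: str = "pile",
) -> dict:
    """Precision/recall of detected loci against planted truth intervals.

    A planted locus is recovered when any detected locus overlaps it;
    a detected locus is a true positive when it overlaps any planted
    locus of any kind (so background clusters count against precision,
    TE/degradation regions do not).  When ``detected_classes`` is given,
    class agreement is scored over matched pairs of the requested kind.
    """
    target = truth_loci[truth_loci["kind"] == kind] if kind else truth_loci
    n_recovered = 0
    for _, row in target.iterrows():
        if any(
            d.chrom == row["chrom"] and d.start < row["end"] and row["start"] < d.end
            for d in detected_loci
        ):
            n_recovered += 1
    recall = n_recovered / len(target) if len(target) else 1.0
    n_true_pos = 0
    class_hits = 0
    class_total = 0
    for i, d in enumerate(detected_loci):
        if _interval_match(d.chrom, d.start, d.end, truth_loci):
            n_true_pos += 1
        match = target[
            (target["chrom"] == d.chrom)
            & (target["start"] < d.end)
            & (d.start < target["end"])
        ]
        if detected_classes is not None and len(match):
            class_total += 1
            if detected_classes[i] == match.iloc[0]["distribution_class"]:
                class_hits += 1
    precision = n_true_pos / len(detected_loci) if detected_loci else 1.0
    report = {"precision": precision, "recall": recall,
              "n_detected": len(detected_loci), "n_planted": int(len(target))}
    if detected_classes is not None:
        report["class_agreement"] = class_hits / class_total if class_total else 1.0
    return report
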