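"""miRNA-like evaluation of candidate loci.

A candidate locus is extended by 50 nt of flanking genome on each side to
form a putative precursor; the up-to-six most abundant distinct fragments
in the locus are proposed as matures; the precursor is folded (default:
thermodynamic nearest-neighbor model at 24 C); the stability of the fold
is scored by an empirical p-value — the proportion of same-length regions
drawn uniformly from the genome whose MFE is strictly lower than the
candidate's, significant below 5% (a very stable candidate leaves few
random regions below it, so small p means more stable than random); and
the mature/star duplex geometry is checked for the Dicer signature of
2-nt 3' overhangs on both ends.  Candidates on a significant hairpin with
a mature sitting on a stem are called miRNA-like; the overhang status
records whether the duplex is canonical (both 3' ends) or one-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .folding import DEFAULT_TEMPERATURE, available_backends, fold, pair_table
from .io_coverage import AlignedRead

__all__ = [
    "HairpinCandidate",
    "build_precursor",
    "propose_matures",
    "empirical_mfe_pvalue",
    "assess_duplex",
    "evaluate_candidate",
]

DEFAULT_FLANK = 50
DEFAULT_N_PERMUTATIONS = 1000
SIGNIFICANCE_LEVEL = 0.05
MAX_MATURES = 6

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def _revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class HairpinCandidate:
    chrom: str
    start: int  # precursor interval (candidate +- flank, clipped)
    end: int
    strand: str
    sequence: str
    structure: str = ""
    mfe: float = 0.0
    empirical_p: Optional[float] = None
    significant: bool = False
    matures: list = field(default_factory=list)  # [(start, end, strand, count)]
    star: Optional[tuple[int, int]] = None  # precursor-relative interval
    overhang_status: str = "none"  # both_3p_2nt | one_side_only | none
    verdict: str = "rejected"  # miRNA_like | rejected
    backend: str = ""
    temperature: float = DEFAULT_TEMPERATURE
    seed: Optional[int] = None


def build_precursor(
    candidate: tuple[str, int, int, str],
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
) -> tuple[str, int, int, str, bool]:
    """Extend (chrom, start, end, strand) by ``flank`` nt on both sides.

    Returns (sequence, start, end, strand, clipped); the sequence is
    reverse-complemented for minus-strand candidates so it reads 5'->3'
    on the transcribed strand.  Intervals running off a chromosome end
    are clipped (flagged).
    """
    chrom, start, end, strand = candidate
    if chrom not in genome:
        raise ValueError(f"chromosome {chrom!r} not in genome")
    seq_len = len(genome[chrom])
    new_start = start - flank
    new_end = end + flank
    clipped = new_start < 0 or new_end > seq_len
    new_start = max(0, new_start)
    new_end = min(seq_len, new_end)
    seq = genome[chrom][new_start:new_end].upper()
    if strand == "-":
        seq = _revcomp(seq)
    return seq.replace("T", "U"), new_start, new_end, strand, clipped


def propose_matures(
    reads: Iterable[AlignedRead], max_matures: int = MAX_MATURES
) -> list[tuple[int, int, str, int]]:
    """The up-to-six most abundant distinct fragments of a locus.

    Fragments are distinct (start, end, strand) triples ranked by read
    count; ties broken by leftmost start, then shortest length.
    """
    counts: dict[tuple[int, int, str], int] = {}
    for r in reads:
        key = (r.start, r.end, r.strand)
        counts[key] = counts.get(key, 0) + 1
    ranked = sorted(
        counts.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1] - kv[0][0])
    )
    return [(s, e, st, c) for (s, e, st), c in ranked[:max_matures]]


def empirical_mfe_pvalue(
    mfe: float,
    length: int,
    genome: Mapping[str, str],
    n: int = DEFAULT_N_PERMUTATIONS,
    seed: Optional[int] = None,
    temperature: float = DEFAULT_TEMPERATURE,
    backend: str = "auto",
) -> float:
    """Fraction of ``n`` random same-length genomic regions with MFE
    strictly below ``mfe``.

    Regions are drawn uniformly over chromosome positions (chromosomes
    weighted by the number of admissible starts), strand chosen with
    probability 1/2, overlaps allowed.  Small p = the candidate fold is
    more stable than random genomic sequence; significant below 5%.
    """
    chroms = [c for c, s in genome.items() if len(s) >= length]
    if not chroms:
        raise ValueError(
            f"region length {length} exceeds the longest chromosome"
        )
    rng = np.random.default_rng(seed)
    starts_per_chrom = np.array([len(genome[c]) - length + 1 for c in chroms], dtype=float)
    probs = starts_per_chrom / starts_per_chrom.sum()
    below = 0
    for _ in range(n):
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        start = int(rng.integers(0, len(genome[chrom]) - length + 1))
        seq = genome[chrom][start : start + length]
        if rng.random() < 0.5:
            seq = _revcomp(seq)
        _, random_mfe = fold(seq.replace("T", "U"), temperature=temperature, backend=backend)
        if random_mfe < mfe:
            below += 1
    return below / n


def _star_from_structure(
    structure: str, mature: tuple[int, int]
) -> Optional[tuple[int, int]]:
    """Star interval as the base-pairing partner span of the mature.

    Follows standard duplex geometry: the partner span of the mature's
    paired positions, extended by 2 nt at its 3' end (the star's own
    2-nt 3' overhang).  None when the mature has no paired bases.
    """
    table = pair_table(structure)
    m0, m1 = mature
    partners = [table[i] for i in range(m0, min(m1, len(table))) if table[i] is not None]
    if not partners:
        return None
    s0, s1 = min(partners), max(partners) + 1
    s1 = min(s1 + 2, len(structure))  # 2-nt 3' overhang of the star
    return s0, s1


def _three_prime_overhang(
    table: Sequence[Optional[int]],
    strand_interval: tuple[int, int],
    partner_interval: tuple[int, int],
) -> Optional[int]:
    """Length of the 3' overhang of one duplex strand.

    The overhang is the number of unpaired 3'-terminal nucleotides of the
    strand beyond its last base paired into the partner span.  None when
    the strand has no base paired to the partner.
    """
    a0, a1 = strand_interval
    p0, p1 = partner_interval
    last_paired = None
    for i in range(a1 - 1, a0 - 1, -1):
        j = table[i] if 0 <= i < len(table) else None
        if j is not None and p0 <= j < p1:
            last_paired = i
            break
    if last_paired is None:
        return None
    return (a1 - 1) - last_paired


def assess_duplex(
    structure: str,
    mature: tuple[int, int],
    star: Optional[tuple[int, int]] = None,
) -> tuple[str, Optional[tuple[int, int]]]:
    """Overhang status of the mature/star duplex on a folded precursor.

    Returns ``(status, star)`` with status ``both_3p_2nt`` when both 3'
    ends extend their partner's pairing by exactly 2 nt (canonical Dicer
    product), ``one_side_only`` when exactly one does, ``none`` when the
    mature is not on a stem or neither end shows the signature.
    Intervals are precursor-relative, half-open.
    """
    table = pair_table(structure)
    if star is None:
        star = _star_from_structure(structure, mature)
    if star is None:
        return "none", None
    over_m = _three_prime_overhang(table, mature, star)
    over_s = _three_prime_overhang(table, star, mature)
    if over_m is None or over_s is None:
        return "none", star
    hits = int(over_m == 2) + int(over_s == 2)
    if hits == 2:
        return "both_3p_2nt", star
    if hits == 1:
        return "one_side_only", star
    return "none", star


def evaluate_candidate(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    reads: Sequence[AlignedRead],
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: Optional[int] = None,
    temperature: float = DEFAULT_TEMPERATURE,
    backend: str = "auto",
) -> HairpinCandidate:
    """Full miRNA-like evaluation of one candidate locus.

    Deterministic given ``seed``; the seed, backend and temperature are
    recorded on the returned candidate.
    """
    seq, p_start, p_end, strand, _clipped = build_precursor(
        (chrom, start, end, strand), genome, flank=flank
    )
    structure, mfe = fold(seq, temperature=temperature, backend=backend)
    used_backend = backend if backend != "auto" else available_backends()[0]
    cand = HairpinCandidate(
        chrom=chrom, start=p_start, end=p_end, strand=strand,
        sequence=seq, structure=structure, mfe=mfe,
        backend=used_backend, temperature=temperature, seed=seed,
    )
    cand.empirical_p = empirical_mfe_pvalue(
        mfe, len(seq), genome, n=n_permutations, seed=seed,
        temperature=temperature, backend=backend,
    )
    cand.significant = cand.empirical_p < SIGNIFICANCE_LEVEL
    matures = propose_matures(reads)
    cand.matures = matures
    if matures:
        m_start, m_end, m_strand, _count = matures[0]
        # genomic -> precursor-relative, strand-oriented coordinates
        if strand == "-":
            rel = (p_end - m_end, p_end - m_start)
        else:
            rel = (m_start - p_start, m_end - p_start)
        rel = (max(rel[0], 0), min(rel[1], len(seq)))
        if rel[1] > rel[0]:
            status, star = assess_duplex(structure, rel)
            cand.overhang_status = status
            cand.star = star
    if cand.significant and cand.star is not None and cand.overhang_status != "none":
        cand.verdict = "miRNA_like"
    return cand
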