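"""Classification of tRNA-derived fragments (tRFs).

Fragments overlapping a tRNA gene are classed by where they sit on the
mature tRNA and how long they are:

* ``3p_short``  — ~19 nt (here 17-22) ending at the mature 3' terminus;
  these normally carry the post-transcriptionally added CCA.
* ``3p_long``   — 30-36 nt anchored at the 3' terminus (no CCA expected).
* ``5p_long``   — 30-36 nt anchored at the 5' end.
* ``half_tRNA`` — spanning the 5' end through the anticodon loop.
* ``dloop_anticodon`` — short fragment over the D loop or anticodon loop
  that is not 3'-anchored.
* ``unclassified`` otherwise.

Anchoring tolerates 3 nt of slack at either terminus (covers templated vs
appended CCA). Precedence when several rules match: half_tRNA > 3'-anchored
classes > 5p_long > dloop_anticodon. CCA status is read from the fragment
*sequence* (the read), not the genome, because CCA may be added to the
trimmed intermediate rather than templated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io_coverage import AlignedRead, TrnaGene

__all__ = ["TrfRecord", "classify_trf", "detect_cca", "classify_reads", "trf_table"]

SHORT_RANGE = (17, 22)
LONG_RANGE = (30, 36)
ANCHOR_SLACK = 3

CLASSES = (
    "3p_short",
    "3p_long",
    "5p_long",
    "half_tRNA",
    "dloop_anticodon",
    "unclassified",
)


@dataclass
class TrfRecord:
    trna: str  # isotype+anticodon id
    five_offset: int  # fragment start relative to mature 5' end
    three_offset: int  # mature 3' terminus minus fragment end
    length: int
    trf_class: str
    cca: str  # 'present' | 'absent' | 'not_applicable'
    library: str = ""
    count: int = 1


def _relative_coords(fragment: AlignedRead, trna: TrnaGene) -> tuple[int, int]:
    """Fragment start/end in mature-tRNA coordinates (strand-oriented)."""
    if trna.strand == "-":
        rel_start = trna.end - fragment.end
        rel_end = trna.end - fragment.start
    else:
        rel_start = fragment.start - trna.start
        rel_end = fragment.end - trna.start
    return rel_start, rel_end


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def classify_trf(
    fragment: AlignedRead,
    trna: TrnaGene,
    slack: int = ANCHOR_SLACK,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
) -> TrfRecord:
    """Assign a fragment overlapping ``trna`` to exactly one tRF class."""
    if fragment.chrom != trna.chrom or not _overlaps(
        fragment.start, fragment.end, trna.start, trna.end
    ):
        raise ValueError(
            f"fragment {fragment.chrom}:{fragment.start}-{fragment.end} does not "
            f"overlap tRNA {trna.name} {trna.chrom}:{trna.start}-{trna.end}"
        )
    trna_len = trna.length
    rel_start, rel_end = _relative_coords(fragment, trna)
    five_off = rel_start
    three_off = trna_len - rel_end
    length = fragment.length
    anchored_5p = abs(five_off) <= slack
    anchored_3p = abs(three_off) <= slack
    ac0, ac1 = trna.arms["anticodon_loop"]
    d0, d1 = trna.arms["d_loop"]

    trf_class = "unclassified"
    # most specific first; a tRNA half is cleaved within the anticodon
    # loop (at the anticodon), so its 3' end must reach at least the
    # middle of the loop — a 30-35 nt 5' fragment merely touching the
    # loop's proximal side is a 5'-tRF, not a half
    ac_mid = (ac0 + ac1) // 2
    if anchored_5p and ac_mid <= rel_end <= (ac1 + slack):
        trf_class = "half_tRNA"
    elif short_range[0] <= length <= short_range[1] and anchored_3p:
        trf_class = "3p_short"
    elif long_range[0] <= length <= long_range[1] and anchored_3p:
        trf_class = "3p_long"
    elif long_range[0] <= length <= long_range[1] and anchored_5p:
        trf_class = "5p_long"
    elif (
        short_range[0] <= length <= short_range[1]
        and not anchored_3p
        and (_overlaps(rel_start, rel_end, d0, d1) or _overlaps(rel_start, rel_end, ac0, ac1))
    ):
        trf_class = "dloop_anticodon"

    record = TrfRecord(
        trna=f"{trna.isotype}{trna.anticodon}" if trna.isotype else trna.name,
        five_offset=five_off,
        three_offset=three_off,
        length=length,
        trf_class=trf_class,
        cca="not_applicable",
        library=fragment.library,
    )
    record.cca = detect_cca(fragment.sequence, record.trf_class)
    return record


def detect_cca(sequence: Optional[str], trf_class: str) -> str:
    """CCA status of a classified fragment.

    ``present`` iff the fragment is 3'-anchored (3p_short/3p_long) and its
    read sequence ends in CCA; ``not_applicable`` for other classes or
    when no sequence is available.
    """
    if trf_class not in ("3p_short", "3p_long"):
        return "not_applicable"
    if not sequence:
        return "not_applicable"
    return "present" if sequence.upper().replace("U", "T").endswith("CCA") else "absent"


def classify_reads(
    reads: Iterable[AlignedRead],
    trnas: Sequence[TrnaGene],
    slack: int = ANCHOR_SLACK,
) -> list[TrfRecord]:
    """Classify every read overlapping any tRNA gene (+- slack)."""
    records = []
    for r in reads:
        for t in trnas:
            if r.chrom == t.chrom and _overlaps(r.start, r.end, t.start - slack, t.end + slack):
                if _overlaps(r.start, r.end, t.start, t.end) or _overlaps(
                    r.start, r.end, t.start - slack, t.end + slack
                ):
                    try:
                        records.append(classify_trf(r, t, slack=slack))
                    except ValueError:
                        continue
                break
    return records


def trf_table(records: Sequence[TrfRecord]):
    """Per-(tRNA, class) summary: length mode, counts per library, CCA status."""
    import pandas as pd
    from collections import Counter

    groups: dict[tuple[str, str], list[TrfRecord]] = {}
    for rec in records:
        groups.setdefault((rec.trna, rec.trf_class), []).append(rec)
    rows = []
    for (trna, cls), recs in sorted(groups.items()):
        lengths = Counter(r.length for r in recs)
        best = max(lengths.values())
        libs = Counter(r.library or "all" for r in recs)
        cca = Counter(r.cca for r in recs)
        rows.append(
            {
                "tRNA": trna,
                "class": cls,
                "length_mode": min(l for l, c in lengths.items() if c == best),
                "n_fragments": len(recs),
                "libraries": ";".join(f"{k}:{v}" for k, v in sorted(libs.items())),
                "cca_present": cca.get("present", 0),
                "cca_absent": cca.get("absent", 0),
            }
        )
    return pd.DataFrame(rows)
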