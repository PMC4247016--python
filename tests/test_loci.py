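"""Locus clustering, distribution classes, candidate filters and merging."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from srnascape.io_coverage import AlignedRead
from srnascape.loci import (
    CandidateLocus,
    SrnaLocus,
    classify_distribution,
    cluster_srna_loci,
    filter_candidates,
    merge_across_libraries,
    shannon_entropy,
)
from .conftest import make_read


def brute_force_clusters(reads, max_gap=100, min_reads=10):
    """Independent single-linkage oracle: union-find over pairwise gaps."""
    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = reads[i], reads[j]
            if a.chrom != b.chrom:
                continue
            gap = max(a.start - b.end, b.start - a.end, 0)
            if gap < max_gap:
                pi, pj = find(i), find(j)
                parent[pi] = pj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return {
        frozenset(g) for g in groups.values() if len(g) >= min_reads
    }


def _partition(loci, reads):
    index = {id(r): i for i, r in enumerate(reads)}
    return {frozenset(index[id(r)] for r in l.reads) for l in loci}


class TestClustering:
    def test_ten_identical_reads_one_locus(self):
        reads = [make_read(start=500, length=21) for _ in range(10)]
        loci = cluster_srna_loci(reads)
        assert len(loci) == 1
        assert loci[0].read_count == 10
        assert (loci[0].start, loci[0].end) == (500, 521)

    def test_nine_reads_below_minimum(self):
        reads = [make_read(start=500, length=21) for _ in range(9)]
        assert cluster_srna_loci(reads) == []

    def test_gap_at_least_max_gap_splits(self):
        # reads [0,20) and [150,170): nearest-end gap 130 >= 100
        reads = [make_read(start=0, length=20) for _ in range(10)]
        reads += [make_read(start=150, length=20) for _ in range(10)]
        loci = cluster_srna_loci(reads)
        assert len(loci) == 2
        assert _partition(loci, reads) == brute_force_clusters(reads)

    def test_gap_just_below_max_gap_joins(self):
        reads = [make_read(start=0, length=20) for _ in range(5)]
        reads += [make_read(start=119, length=20) for _ in range(5)]  # gap 99
        loci = cluster_srna_loci(reads)
        assert len(loci) == 1 and loci[0].read_count == 10

    @given(st.data())
    def test_matches_single_linkage_oracle(self, data):
        n = data.draw(st.integers(0, 50))
        starts = data.draw(
            st.lists(st.integers(0, 2000), min_size=n, max_size=n)
        )
        reads = [make_read(start=s, length=20) for s in starts]
        min_reads = data.draw(st.integers(1, 5))
        loci = cluster_srna_loci(reads, max_gap=100, min_reads=min_reads)
        assert _partition(loci, reads) == brute_force_clusters(
            reads, max_gap=100, min_reads=min_reads
        )

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        reads = [make_read(start=int(s), length=20) for s in rng.integers(0, 5000, 80)]
        loci = cluster_srna_loci(reads, min_reads=3)
        clustered = sum(l.read_count for l in loci)
        unclustered = len(reads) - clustered
        assert clustered + unclustered == len(reads)
        assert unclustered >= 0


class TestDistributionClass:
    def test_identical_plus_strand_reads_are_pile(self):
        reads = [make_read(start=100, length=24) for _ in range(100)]
        locus = cluster_srna_loci(reads)[0]
        assert locus.strand_fraction == 1.0
        assert locus.localization == 1.0
        assert classify_distribution(locus) == "PILE"

    def test_scattered_both_strand_reads_are_distributed(self):
        rng = np.random.default_rng(1)
        reads = [
            make_read(start=int(s), length=25, strand="+" if i % 2 else "-")
            for i, s in enumerate(rng.integers(0, 2000, 100))
        ]
        locus = SrnaLocus(chrom="chr1", start=0, end=2025, reads=reads)
        assert classify_distribution(locus) == "DISTRIBUTED"

    def test_synthetic_te_locus_is_distributed(self, bundle, usable_reads):
        """Generator truth: both-strand TE coverage classifies DISTRIBUTED."""
        te = bundle.truth["te"]
        te = te[te["methylated"] == 1].iloc[0]
        members = [
            r for r in usable_reads
            if r.chrom == te["chrom"] and r.start < te["end"] and te["start"] < r.end
        ]
        locus = SrnaLocus(
            chrom=te["chrom"], start=int(te["start"]), end=int(te["end"]),
            reads=members,
        )
        assert classify_distribution(locus) == "DISTRIBUTED"

    def test_dominant_length_tie_broken_short(self):
        reads = [make_read(start=0, length=24) for _ in range(5)]
        reads += [make_read(start=0, length=25) for _ in range(5)]
        locus = SrnaLocus(chrom="chr1", start=0, end=25, reads=reads)
        assert locus.dominant_length == 24


class TestCandidateFilters:
    genome = {"chr1": ("ACGT" * 3000)[:10_000]}

    def _pile(self, start=5000, length=24, n=50):
        reads = [make_read(start=start, length=length) for _ in range(n)]
        return SrnaLocus(chrom="chr1", start=start, end=start + length, reads=reads)

    def test_entropy_rich_intergenic_pile_retained(self, tiny_annotations):
        cands = filter_candidates([self._pile()], self.genome, tiny_annotations)
        assert len(cands) == 1
        assert cands[0].candidate_type == "intergenic-novel"

    def test_low_complexity_sequence_rejected(self, tiny_annotations):
        genome = {"chr1": "A" * 10_000}
        cands = filter_candidates([self._pile()], genome, tiny_annotations)
        assert cands == []
        assert shannon_entropy("A" * 24) == 0.0

    def test_dominant_length_outside_19_29_rejected(self, tiny_annotations):
        cands = filter_candidates(
            [self._pile(length=31)], self.genome, tiny_annotations
        )
        assert cands == []

    def test_trna_overlap_typed_trna_associated(self, tiny_annotations):
        # pile inside the tRNA at 1000-1076 (also inside repeat TE2:
        # tRNA typing wins)
        cands = filter_candidates(
            [self._pile(start=1050, length=20)], self.genome, tiny_annotations
        )
        assert len(cands) == 1
        assert cands[0].candidate_type == "tRNA-associated"

    def test_missing_genome_sequence_errors(self, tiny_annotations):
        locus = SrnaLocus(
            chrom="chrZ", start=0, end=24, reads=[make_read(chrom="chrZ")]
        )
        with pytest.raises(ValueError, match="genome sequence unavailable"):
            filter_candidates([locus], self.genome, tiny_annotations)


class TestMergeAcrossLibraries:
    def _cand(self, start, end, lib):
        reads = [make_read(start=start, length=min(end - start, 24), library=lib)
                 for _ in range(10)]
        locus = SrnaLocus(chrom="chr1", start=start, end=end, reads=reads)
        return CandidateLocus(
            locus=locus, passed_filters={}, candidate_type="intergenic-novel",
            libraries={lib},
        )

    def test_same_locus_two_libraries_support_two(self):
        merged = merge_across_libraries(
            {"NL": [self._cand(100, 150, "NL")], "HL": [self._cand(100, 150, "HL")]}
        )
        assert len(merged) == 1
        assert merged[0].support == 2
        assert merged[0].libraries == {"NL", "HL"}

    def test_disjoint_loci_stay_separate(self):
        merged = merge_across_libraries(
            {"NL": [self._cand(100, 150, "NL")], "HL": [self._cand(500, 550, "HL")]}
        )
        assert len(merged) == 2
        assert all(m.support == 1 for m in merged)

    def test_overlapping_intervals_union(self):
        merged = merge_across_libraries(
            {"NL": [self._cand(100, 150, "NL")], "HL": [self._cand(140, 200, "HL")]}
        )
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 200)

    def test_idempotent_and_order_independent(self):
        sets = {
            "NL": [self._cand(100, 150, "NL"), self._cand(900, 950, "NL")],
            "HL": [self._cand(140, 200, "HL")],
            "LL": [self._cand(905, 940, "LL")],
        }
        merged1 = merge_across_libraries(sets)
        # permuted library order
        merged2 = merge_across_libraries(dict(reversed(list(sets.items()))))
        key = lambda ms: sorted((m.chrom, m.start, m.end, m.support) for m in ms)
        assert key(merged1) == key(merged2)
        # merging the merged result again changes nothing
        remerged = merge_across_libraries({"all": merged1})
        assert key(remerged) == [
            (c, s, e, 1) for (c, s, e, _sup) in key(merged1)
        ]
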