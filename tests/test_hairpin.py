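"""Precursor building, mature proposal, folding and duplex geometry."""

import numpy as np
import pytest
from Bio.Seq import Seq

from srnascape.folding import available_backends, fold, pair_table
from srnascape.hairpin import (
    assess_duplex,
    build_precursor,
    empirical_mfe_pvalue,
    evaluate_candidate,
    propose_matures,
)
from srnascape.synthetic import make_hairpin_genome
from .conftest import make_read

GENOME = {"chr1": ("ACGTTGCA" * 2000)[:10_000]}


class TestBuildPrecursor:
    def test_plus_strand_flank_arithmetic(self):
        seq, start, end, strand, clipped = build_precursor(
            ("chr1", 100, 150, "+"), GENOME, flank=50
        )
        assert (start, end) == (50, 200)
        assert len(seq) == 150
        assert not clipped

    def test_clipped_at_chromosome_start(self):
        seq, start, end, _, clipped = build_precursor(
            ("chr1", 20, 60, "+"), GENOME, flank=50
        )
        assert start == 0 and clipped

    def test_minus_strand_reverse_complemented(self):
        seq, start, end, _, _ = build_precursor(("chr1", 100, 150, "-"), GENOME)
        expected = str(
            Seq(GENOME["chr1"][50:200]).reverse_complement()
        ).replace("T", "U")
        assert seq == expected


class TestProposeMatures:
    def test_top_six_by_abundance(self):
        reads = []
        for i in range(8):
            for _ in range(10 - i):
                reads.append(make_read(start=100 + 5 * i, length=21))
        matures = propose_matures(reads)
        assert len(matures) == 6
        counts = [m[3] for m in matures]
        assert counts == sorted(counts, reverse=True)
        assert matures[0][0] == 100

    def test_rank6_tie_broken_leftmost_then_shortest(self):
        reads = [make_read(start=200, length=25), make_read(start=100, length=25),
                 make_read(start=100, length=21)]
        matures = propose_matures(reads, max_matures=2)
        assert matures[0][:2] == (100, 121)  # leftmost, then shortest
        assert matures[1][:2] == (100, 125)

    def test_single_fragment(self):
        assert len(propose_matures([make_read()])) == 1


class TestFold:
    def test_gc_stem_pairs(self):
        structure, mfe = fold("GGGGAAAACCCC")
        assert "(" in structure and ")" in structure
        assert mfe < 0
        table = pair_table(structure)
        assert any(
            table[i] is not None and table[i] >= 8 for i in range(4)
        )

    def test_homopolymer_no_pairs(self):
        structure, mfe = fold("AAAAAAAA")
        assert structure == "." * 8
        assert mfe == 0.0

    def test_deterministic(self):
        seq = "GCGCGCAAAUUUGCGCGC"
        assert fold(seq) == fold(seq)

    def test_backends_agree_on_stem_presence(self):
        seq = "GGGGGGAAAAAACCCCCC"
        for backend in available_backends():
            structure, _ = fold(seq, backend=backend)
            assert structure.count("(") >= 4

    def test_temperature_recorded_model(self):
        # colder folding can only stabilize or keep the MFE
        if "viennarna" not in available_backends():
            pytest.skip("thermodynamic backend unavailable")
        seq = "GGGCGCAAAUUUGCGCCC"
        _, mfe24 = fold(seq, temperature=24)
        _, mfe37 = fold(seq, temperature=37)
        assert mfe24 <= mfe37


class TestEmpiricalP:
    def test_extremes(self):
        genome = {"chr1": ("ACGT" * 500)}
        assert empirical_mfe_pvalue(-1e9, 40, genome, n=20, seed=0) == 0.0
        assert empirical_mfe_pvalue(1e9, 40, genome, n=20, seed=0) == 1.0

    def test_monotone_in_stability(self):
        rng = np.random.default_rng(4)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 4000))}
        ps = [
            empirical_mfe_pvalue(m, 60, genome, n=50, seed=9)
            for m in (-30.0, -10.0, -2.0, 0.0)
        ]
        assert ps == sorted(ps)

    def test_length_longer_than_genome_errors(self):
        with pytest.raises(ValueError, match="longest chromosome"):
            empirical_mfe_pvalue(-5.0, 100, {"chr1": "ACGU" * 10}, n=5, seed=0)

    def test_seed_reproducible(self):
        genome = {"chr1": ("ACGT" * 500)}
        a = empirical_mfe_pvalue(-8.0, 50, genome, n=30, seed=123)
        b = empirical_mfe_pvalue(-8.0, 50, genome, n=30, seed=123)
        assert a == b


class TestAssessDuplex:
    @staticmethod
    def _hairpin_structure(n, pairs):
        """Dot-bracket of length n with pairs (i, j)."""
        s = ["."] * n
        for i, j in pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)

    def test_canonical_two_nt_overhangs_both_sides(self):
        # stem pairs 0..7 <-> 21..14; mature [0,10) has tail 8,9 (2 nt);
        # star [14,24) has tail 22,23 (2 nt beyond its pairing at 21)
        structure = self._hairpin_structure(24, [(k, 21 - k) for k in range(8)])
        status, _ = assess_duplex(structure, (0, 10), (14, 24))
        assert status == "both_3p_2nt"

    def test_blunt_end_one_side_only(self):
        # mature fully paired (blunt 3' end), star keeps its 2-nt tail
        structure = self._hairpin_structure(24, [(k, 21 - k) for k in range(10)])
        status, _ = assess_duplex(structure, (0, 10), (12, 24))
        assert status == "one_side_only"

    def test_no_signature_either_side(self):
        # both ends blunt
        structure = self._hairpin_structure(24, [(k, 21 - k) for k in range(10)])
        status, _ = assess_duplex(structure, (0, 10), (12, 22))
        assert status == "none"

    def test_mature_in_loop_is_none(self):
        structure = "((((....))))"
        status, star = assess_duplex(structure, (4, 8))
        assert status == "none"
        assert star is None

    def test_star_derived_from_structure(self):
        structure = self._hairpin_structure(24, [(k, 21 - k) for k in range(8)])
        status, star = assess_duplex(structure, (0, 10))
        # partner span 14-22 plus the 2-nt 3' tail
        assert star == (14, 24)
        assert status == "both_3p_2nt"


class TestEvaluateCandidate:
    def test_planted_hairpin_significant_and_reproducible(self):
        rng = np.random.default_rng(8)
        genome, (chrom, start, end) = make_hairpin_genome(rng, genome_length=8000)
        reads = [
            make_read(chrom=chrom, start=start + 2, length=21) for _ in range(30)
        ]
        a = evaluate_candidate(
            chrom, start, end, "+", reads, genome, n_permutations=60, seed=42
        )
        b = evaluate_candidate(
            chrom, start, end, "+", reads, genome, n_permutations=60, seed=42
        )
        assert a.empirical_p == b.empirical_p
        assert a.structure == b.structure and a.mfe == b.mfe
        assert a.empirical_p < 0.05
        assert a.seed == 42 and a.backend in ("viennarna", "nussinov")
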