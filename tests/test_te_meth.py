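"""RPKM, methylation level, binning, expression classes and the test battery."""

import itertools

import numpy as np
import pytest
from scipy import stats

from srnascape.io_coverage import Feature
from srnascape.te_meth import (
    RegionStats,
    association_tests,
    bin_rpkm,
    expression_class,
    five_prime_composition,
    methylation_level,
    region_read_count,
    rpkm,
    _mannwhitney_one_sided,
)
from .conftest import make_read


def mw_exact_p_greater(x, y):
    """Brute-force one-sided Mann-Whitney p by full enumeration.

    p = fraction of all C(n+m, n) group assignments of the pooled values
    whose U statistic (for the first group) is >= the observed U.
    """

    def u_stat(a, b):
        u = 0.0
        for ai in a:
            for bj in b:
                u += (ai > bj) + 0.5 * (ai == bj)
        return u

    pooled = list(x) + list(y)
    observed = u_stat(x, y)
    n = len(x)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(a, b) >= observed - 1e-12:
            count += 1
    return count / total


class TestRpkm:
    def test_closed_form(self):
        assert rpkm(10, 1000, 1_000_000) == pytest.approx(10.0)

    def test_zero_reads(self):
        assert rpkm(0, 1000, 1_000_000) == 0.0

    def test_scale_invariance(self):
        assert rpkm(20, 1000, 2_000_000) == pytest.approx(
            rpkm(10, 1000, 1_000_000)
        )

    def test_zero_length_region_errors(self):
        with pytest.raises(ValueError, match="zero-length"):
            rpkm(10, 0, 1_000_000)

    def test_region_count_is_weighted(self):
        reads = [make_read(start=100, length=20, multiplicity=4)]
        assert region_read_count(("chr1", 0, 1000), reads) == pytest.approx(0.25)
        assert region_read_count(("chr1", 0, 1000), reads, weighted=False) == 1.0


class TestMethylationLevel:
    probes = [
        Feature("chr1", 10, 12, ".", "p1", {"methylated": 1}),
        Feature("chr1", 20, 22, ".", "p2", {"methylated": 1}),
        Feature("chr1", 30, 32, ".", "p3", {"methylated": 0}),
    ]

    def test_two_of_three(self):
        assert methylation_level(("chr1", 0, 100), self.probes) == pytest.approx(2 / 3)

    def test_no_probes_flagged_undefined(self):
        assert methylation_level(("chr1", 500, 600), self.probes) is None

    def test_nested_region_uses_own_probes_only(self):
        assert methylation_level(("chr1", 25, 100), self.probes) == pytest.approx(0.0)
        assert methylation_level(("chr1", 0, 15), self.probes) == pytest.approx(1.0)


class TestBinsAndExpression:
    @pytest.mark.parametrize(
        "value,expected",
        [(4.9, "low"), (5.0, "middle"), (7.0, "middle"), (10.0, "middle"),
         (10.5, "high"), (0.0, "low"), (1e6, "high")],
    )
    def test_rpkm_bins(self, value, expected):
        assert bin_rpkm(value) == expected

    def test_percentile_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(2.0, 20.0, size=100).tolist()
        labels = expression_class(values)
        # oracle: numpy percentile on the sorted copy
        threshold = float(np.percentile(sorted(values), 15.0))
        expected = ["low" if v <= threshold else "expressed" for v in values]
        assert labels == expected
        assert 10 <= labels.count("low") <= 20

    def test_all_equal_values_all_low(self):
        assert expression_class([5.0] * 7) == ["low"] * 7

    def test_reference_population_threshold(self):
        labels = expression_class([0.1, 50.0], reference=list(range(100)))
        assert labels == ["low", "expressed"]


class TestMannWhitney:
    def test_clean_separation_exact_enumeration(self):
        """{1,2,3} vs {10,11,12}: exact p from full enumeration."""
        p_oracle = mw_exact_p_greater([1, 2, 3], [10, 11, 12])
        _, p_impl = _mannwhitney_one_sided([1, 2, 3], [10, 11, 12])
        assert p_impl == pytest.approx(p_oracle)
        # the reversed direction is 1/20
        p_rev = mw_exact_p_greater([10, 11, 12], [1, 2, 3])
        _, p_rev_impl = _mannwhitney_one_sided([10, 11, 12], [1, 2, 3])
        assert p_rev == pytest.approx(1 / 20)
        assert p_rev_impl == pytest.approx(p_rev)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_groups_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(3, 6)), int(rng.integers(3, 6))
        # distinct values to stay in the exact regime
        pool = rng.permutation(100)[: n + m].astype(float)
        x, y = pool[:n].tolist(), pool[n:].tolist()
        _, p_impl = _mannwhitney_one_sided(x, y)
        assert p_impl == pytest.approx(mw_exact_p_greater(x, y))


class TestAssociationBattery:
    def _regions(self):
        rng = np.random.default_rng(2)
        regions = []
        for i in range(8):
            silenced = i < 4
            regions.append(
                RegionStats(
                    chrom="chr1", start=i * 1000, end=i * 1000 + 900,
                    name=f"te{i}",
                    srna_rpkm=float(rng.uniform(50, 80)) if silenced else float(rng.uniform(0, 2)),
                    methylation_level=0.9 if silenced else 0.1,
                    expression=0.1 if silenced else 50.0,
                    expression_class="low" if silenced else "expressed",
                )
            )
        return regions

    def test_silenced_regions_show_higher_coverage(self):
        report = association_tests(self._regions())
        assert report["mw_expression"]["pvalue"] < 0.05
        assert report["mw_methylation"]["pvalue"] < 0.05
        assert report["spearman"]["rho"] > 0
        assert report["pearson"]["r"] > 0

    def test_perfectly_monotone_pairs_spearman_one(self):
        regions = [
            RegionStats(chrom="chr1", start=i, end=i + 100, srna_rpkm=float(i),
                        methylation_level=i / 10.0)
            for i in range(1, 9)
        ]
        report = association_tests(regions)
        assert report["spearman"]["rho"] == pytest.approx(1.0)

    def test_identical_groups_not_significant(self):
        regions = [
            RegionStats(chrom="chr1", start=i, end=i + 100, srna_rpkm=5.0 + i,
                        methylation_level=0.5,
                        expression_class="low" if i % 2 else "expressed")
            for i in range(8)
        ]
        report = association_tests(regions)
        assert report["mw_expression"]["pvalue"] >= 0.5 or report[
            "mw_expression"
        ]["pvalue"] > 0.05
        assert report["spearman"] is None  # constant methylation

    def test_small_groups_reported_na_with_warning(self):
        regions = [
            RegionStats(chrom="chr1", start=0, end=100, srna_rpkm=1.0,
                        expression_class="low"),
            RegionStats(chrom="chr1", start=200, end=300, srna_rpkm=2.0,
                        expression_class="expressed"),
        ]
        report = association_tests(regions)
        assert report["mw_expression"] is None
        assert any("too small" in w for w in report["warnings"])

    def test_library_correlation_matrix(self):
        regions = self._regions()
        reads = {
            "NL": [make_read(start=100, length=20) for _ in range(5)],
            "HL": [make_read(start=100, length=20) for _ in range(5)],
        }
        report = association_tests(regions, reads)
        mat = report["library_correlation"]
        assert mat.loc["NL", "NL"] == 1.0
        assert mat.loc["NL", "HL"] == mat.loc["HL", "NL"]


class TestFivePrimeComposition:
    def test_simple_frequencies(self):
        reads = [
            make_read(length=21, sequence="T" + "A" * 20),
            make_read(length=21, sequence="TCC" + "A" * 18),
            make_read(length=21, sequence="G" + "A" * 20),
        ]
        comp = five_prime_composition(reads)
        assert comp.loc[1, "U"] == pytest.approx(2 / 3)
        assert comp.loc[1, "G"] == pytest.approx(1 / 3)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        reads = [
            make_read(length=21, sequence="".join(rng.choice(list("ACGT"), 21)))
            for _ in range(50)
        ]
        comp = five_prime_composition(reads)
        assert np.allclose(comp.sum(axis=1), 1.0)
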