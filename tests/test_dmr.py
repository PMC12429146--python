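import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats

from conftest import make_sample
from cfmeth.core import GeneModel
from cfmeth.dmr import (
    DMRCriteria,
    GeneIndex,
    annotate_dmr,
    call_dmrs,
    coverage_filter,
    fisher_exact_two_sided,
    mean_diff,
    overlap_test,
)
from cfmeth.regions import MethylRegion, build_regions
from cfmeth.simulate import SimConfig, simulate_cohort


def exact_two_sided_fisher(a, b, c, d):
    """Exact-rational enumeration oracle with the same inclusion rule."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    kmin, kmax = max(0, c1 - r2), min(c1, r1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)}
    w_obs = weights[a]
    tol_num, tol_den = 10**7 + 1, 10**7
    total = sum(w for w in weights.values() if w * tol_den <= w_obs * tol_num)
    return Fraction(total, math.comb(n, c1))


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_two_sided([[5, 5], [5, 5]]) == 1.0

    def test_perfect_separation(self):
        # margins (10,10)/(10,10): only X=10 and X=0 qualify, each 1/C(20,10)
        p = fisher_exact_two_sided([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_worked_table(self):
        p = fisher_exact_two_sided([[8, 2], [2, 8]])
        assert p == pytest.approx(4252 / 184756, rel=1e-9)

    @pytest.mark.parametrize("table", [[[0, 0], [3, 4]], [[1, 0], [2, 0]]])
    def test_zero_margin_gives_one(self, table):
        assert fisher_exact_two_sided(table) == 1.0

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[1, -1], [2, 3]])

    def test_matches_enumeration_oracle_small_margins(self, rng):
        for _ in range(150):
            a, b, c, d = rng.integers(0, 13, size=4)
            p = fisher_exact_two_sided([[a, b], [c, d]])
            exact = float(exact_two_sided_fisher(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(exact, rel=1e-9)

    def test_matches_scipy_reference(self, rng):
        for _ in range(100):
            t = rng.integers(0, 40, size=(2, 2))
            ours = fisher_exact_two_sided(t)
            ref = scipy.stats.fisher_exact(t, alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)


def region_from_counts(counts, positions=(100, 150, 199)):
    return MethylRegion(
        region_id="r",
        chrom="chrS",
        start=positions[0],
        end=positions[-1] + 1,
        cpg_positions=np.array(positions),
        mode=float(np.mean(positions)),
        per_sample_counts=counts,
    )


class TestMeanDiff:
    def test_simple_difference(self):
        region = region_from_counts(
            {
                "c1": (8, 10), "c2": (8, 10), "c3": (8, 10),
                "n1": (5, 10), "n2": (5, 10), "n3": (5, 10), "n4": (5, 10),
            }
        )
        samples = [make_sample(f"c{i}", "cancer", [(100, 1, 2)]) for i in (1, 2, 3)]
        samples += [make_sample(f"n{i}", "normal", [(100, 1, 2)]) for i in (1, 2, 3, 4)]
        assert mean_diff(region, samples) == pytest.approx(0.30)

    def test_identical_groups_zero(self):
        region = region_from_counts({"c1": (5, 10), "c2": (5, 10), "n1": (5, 10), "n2": (5, 10)})
        samples = [make_sample(s, g, [(100, 1, 2)]) for s, g in
                   [("c1", "cancer"), ("c2", "cancer"), ("n1", "normal"), ("n2", "normal")]]
        assert mean_diff(region, samples) == 0.0

    def test_uncovered_sample_excluded(self):
        region = region_from_counts(
            {"c1": (6, 10), "c2": (9, 10), "c3": (0, 0),
             "n1": (5, 10), "n2": (5, 10)}
        )
        samples = [make_sample(s, "cancer", [(100, 1, 2)]) for s in ("c1", "c2", "c3")]
        samples += [make_sample(s, "normal", [(100, 1, 2)]) for s in ("n1", "n2")]
        assert mean_diff(region, samples) == pytest.approx(0.75 - 0.5)


class TestCoverageFilter:
    def _cohort(self, totals_at_100, totals_at_150):
        # 7 samples, three CpGs; the third CpG always well covered
        samples = []
        for i in range(7):
            group = "cancer" if i < 3 else "normal"
            rows = [
                (100, 0, totals_at_100[i]),
                (150, 0, totals_at_150[i]),
                (199, 0, 10),
                (210, 0, 10),
                (220, 0, 10),
            ]
            samples.append(make_sample(f"s{i}", group, rows))
        regions, _ = build_regions(samples)
        return samples, regions[0]

    def test_2n_rule_keeps_and_drops(self):
        # summed total 14 >= 2*7 retained; 13 dropped
        samples, region = self._cohort([2] * 7, [2, 2, 2, 2, 2, 2, 1])
        out = coverage_filter(region, samples, DMRCriteria())
        assert out is not None
        assert 150 not in out.cpg_positions
        assert 100 in out.cpg_positions

    def test_region_discarded_when_too_few_survive(self):
        samples, region = self._cohort([1] * 7, [1] * 7)
        out = coverage_filter(region, samples, DMRCriteria(min_cpg=4))
        assert out is None


class TestCallDmrs:
    def _two_group_cohort(self, case_rows, ctrl_rows):
        samples = [make_sample(f"c{i}", "cancer", case_rows) for i in range(2)]
        samples += [make_sample(f"n{i}", "normal", ctrl_rows) for i in range(2)]
        regions, _ = build_regions(samples)
        return samples, regions

    def test_small_diff_not_called_despite_tiny_p(self):
        pos = [100, 150, 199]
        case = [(p, 5500, 10000) for p in pos]
        ctrl = [(p, 5000, 10000) for p in pos]
        samples, regions = self._two_group_cohort(case, ctrl)
        # Fisher on the pooled table is astronomically significant...
        from cfmeth.dmr import fisher_exact_two_sided as f
        assert f([[33000, 27000], [30000, 30000]]) < 1e-8
        # ...but the 5-point difference fails the |diff| >= 10% filter
        assert call_dmrs(regions, samples) == []

    def test_large_diff_not_called_when_p_too_big(self):
        pos = [100, 150, 199]
        case = [(p, 7, 10) for p in pos]
        ctrl = [(p, 4, 10) for p in pos]
        samples, regions = self._two_group_cohort(case, ctrl)
        called = call_dmrs(regions, samples)
        assert called == []  # diff 0.3 but pooled p ~ 1.7e-3 > 1e-8

    def test_single_group_rejected(self):
        samples = [make_sample(f"s{i}", "normal", [(100, 1, 2)]) for i in range(3)]
        with pytest.raises(ValueError, match="single group"):
            call_dmrs([], samples)

    def test_min_diff_monotonicity_and_direction(self, small_cohort):
        _, samples, _ = small_cohort
        regions, _ = build_regions(samples)
        loose = call_dmrs(regions, samples, DMRCriteria(min_abs_diff=0.10))
        tight = call_dmrs(regions, samples, DMRCriteria(min_abs_diff=0.25))
        assert len(tight) <= len(loose)
        assert {d.region.region_id for d in tight} <= {d.region.region_id for d in loose}
        assert all(d.direction in ("hyper", "hypo") for d in loose)
        signs = [(d.direction == "hyper") == (d.mean_diff > 0) for d in loose]
        assert all(signs)
        # sorted by p ascending
        ps = [d.p_value for d in loose]
        assert ps == sorted(ps)

    def test_recovers_planted_dmrs(self, small_cohort):
        cfg, samples, truth = small_cohort
        regions, _ = build_regions(samples)
        dmrs = call_dmrs(regions, samples)
        planted = truth.planted_dmrs
        hits = 0
        for isl in planted:
            if any(
                d.region.start < isl.end and d.region.end > isl.start
                for d in dmrs
            ):
                hits += 1
        assert hits / len(planted) >= 0.9

    def test_permuted_labels_call_nothing(self):
        cfg = SimConfig(seed=21, n_islands=200, dmr_fraction=0.0,
                        n_e_genes=0, n_m_genes=0)
        samples, _, _ = simulate_cohort(cfg)
        # rotate group labels so each "group" mixes true groups
        labels = [s.group for s in samples]
        permuted = labels[3:] + labels[:3]
        for s, g in zip(samples, permuted):
            s.group = g
        regions, _ = build_regions(samples)
        assert len(call_dmrs(regions, samples)) <= 1


class TestAnnotation:
    GENES = [
        GeneModel("PLUS", "chrS", 10_000, 20_000, "+"),
        GeneModel("MINUS", "chrS", 40_000, 50_000, "-"),
    ]

    def _dmr(self, start, end):
        from cfmeth.dmr import DMRecord

        return DMRecord(
            region=region_from_counts({}, (start, (start + end) // 2, end - 1)),
            table=np.zeros((2, 2), dtype=int),
            p_value=1e-10,
            mean_diff=0.2,
            direction="hyper",
        )

    def test_promoter_upstream_of_plus_gene(self):
        d = annotate_dmr(self._dmr(6000, 6200), self.GENES)
        assert d.annotation == "promoter"
        assert d.gene_id == "PLUS"
        assert d.tss_distance == pytest.approx(-3900)

    def test_promoter_upstream_of_minus_gene(self):
        d = annotate_dmr(self._dmr(52_000, 52_200), self.GENES)
        assert d.annotation == "promoter"
        assert d.gene_id == "MINUS"
        assert d.tss_distance == pytest.approx(-(52_100 - 49_999))

    def test_gene_body(self):
        d = annotate_dmr(self._dmr(12_000, 12_300), self.GENES)
        assert (d.annotation, d.gene_id) == ("gene body", "PLUS")

    def test_intergenic(self):
        d = annotate_dmr(self._dmr(2_000_000, 2_000_200), self.GENES)
        assert (d.annotation, d.gene_id) == ("intergenic", "")
        assert d.tss_distance is None

    def test_promoter_precedence_over_body(self):
        # region in the body of PLUS and the promoter of a nested gene
        genes = self.GENES + [GeneModel("NESTED", "chrS", 17_000, 18_000, "+")]
        d = annotate_dmr(self._dmr(12_500, 12_700), genes)
        assert d.annotation == "promoter"
        assert d.gene_id == "NESTED"


class TestOverlapTest:
    def test_full_overlap(self):
        assert overlap_test(10, 10, 10, 20) == pytest.approx(1 / 184756, rel=1e-9)

    def test_zero_overlap_total_probability(self):
        assert overlap_test(5, 10, 0, 30) == 1.0

    def test_empty_query(self):
        assert overlap_test(0, 10, 0, 30) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_test(5, 5, 6, 30)
        with pytest.raises(ValueError):
            overlap_test(40, 5, 5, 30)
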