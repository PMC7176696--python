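import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ibdnet import (
    FocalStudyConfig,
    PopulationTable,
    binomial_upper_pvalue,
    enrichment_report,
    focal_segment_counts,
    simulate_focal_study,
    tsbh_adjust,
)

from conftest import make_segment


@pytest.fixture
def focal_table():
    return PopulationTable.from_mapping(
        {"F": "focal", "a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"}
    )


class TestFocalCounts:
    def test_counts_by_partner_population(self, focal_table):
        segs = [
            make_segment(a="F", b="a1"),
            make_segment(a="a2", b="F"),
            make_segment(a="F", b="b1"),
        ]
        observed, total, ignored = focal_segment_counts(segs, "F", focal_table)
        assert observed == {"focal": 0, "A": 2, "B": 1}
        assert total == 3 and ignored == 0

    def test_non_focal_segments_excluded_with_count(self, focal_table):
        segs = [make_segment(a="F", b="a1"), make_segment(a="a1", b="b1")]
        observed, total, ignored = focal_segment_counts(segs, "F", focal_table)
        assert total == 1 and ignored == 1

    def test_no_focal_segments(self, focal_table):
        observed, total, _ = focal_segment_counts([], "F", focal_table)
        assert total == 0 and all(v == 0 for v in observed.values())

    def test_missing_focal_errors(self, focal_table):
        with pytest.raises(KeyError, match="GHOST"):
            focal_segment_counts([], "GHOST", focal_table)

    def test_individuals_mode_counts_distinct_partners(self, focal_table):
        segs = [make_segment(a="F", b="a1"), make_segment(a="F", b="a1", chrom="2")]
        observed, total, _ = focal_segment_counts(segs, "F", focal_table, trials="individuals")
        assert observed["A"] == 1 and total == 1


class TestBinomialTail:
    def test_zero_observed_is_whole_distribution(self):
        assert binomial_upper_pvalue(0, 10, 0.3) == 1.0

    def test_exact_value_n5_p02_obs3(self):
        # sum_{k=3}^{5} C(5,k) 0.2^k 0.8^(5-k) = 0.05792
        assert binomial_upper_pvalue(3, 5, 0.2) == pytest.approx(0.05792, abs=1e-12)

    def test_degenerate_p_one(self):
        assert binomial_upper_pvalue(5, 5, 1.0) == 1.0

    def test_observed_above_support_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            p = binomial_upper_pvalue(7, 5, 0.5)
        assert p == pytest.approx(0.5**5)

    @pytest.mark.parametrize("bad", [(-1, 5, 0.5), (2, 5, 1.5), (2, 5, -0.1)])
    def test_invalid_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            binomial_upper_pvalue(*bad)

    def test_agrees_with_brute_force_enumeration(self):
        # every (n <= 20, observed, p) against direct pmf summation
        for n in range(1, 21):
            for p in np.arange(0.1, 1.0, 0.1):
                pmf = [
                    len(list(itertools.combinations(range(n), k))) * p**k * (1 - p) ** (n - k)
                    for k in range(n + 1)
                ]
                for obs in range(n + 1):
                    assert binomial_upper_pvalue(obs, n, p) == pytest.approx(
                        sum(pmf[obs:]), abs=1e-12
                    )


class TestTSBH:
    def test_all_ones_reject_nothing(self):
        res = tsbh_adjust([1.0] * 8)
        assert not res.reject.any() and (res.p_adjusted == 1.0).all()
        assert res.m0 == 8

    def test_single_test_uses_stage_one_level(self):
        # m = 1: rejected iff p <= alpha/(1+alpha) ~ 0.0476
        assert tsbh_adjust([0.01], alpha=0.05).reject.all()
        assert not tsbh_adjust([0.049], alpha=0.05).reject.any()

    def test_r1_zero_matches_plain_bh_at_deflated_level(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.3, 1.0, size=15)
        res = tsbh_adjust(p, alpha=0.05)
        assert res.r1 == 0 and res.m0 == 15
        assert not res.reject.any()
        # adjusted values equal plain BH when m0 = m
        order = np.argsort(p)
        bh = np.minimum.accumulate(
            (len(p) * p[order] / np.arange(1, len(p) + 1))[::-1]
        )[::-1]
        assert res.p_adjusted[order] == pytest.approx(np.clip(bh, 0, 1))

    def test_rejections_match_statsmodels_two_stage(self):
        multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.uniform(size=12) ** rng.integers(1, 4)
            res = tsbh_adjust(p, alpha=0.05)
            reject_sm, padj_sm = multipletests(p, alpha=0.05, method="fdr_tsbky")[:2]
            assert (res.reject == reject_sm).all()
            if 0 < res.m0 < 12:
                # statsmodels rescales by (1+alpha) so rejection reads p <= alpha
                assert res.p_adjusted * 1.05 == pytest.approx(np.clip(padj_sm, 0, 1.05))

    def test_adjusted_values_invariant_to_ordering(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=10)
        perm = rng.permutation(10)
        res = tsbh_adjust(p)
        res_p = tsbh_adjust(p[perm])
        assert res_p.p_adjusted == pytest.approx(res.p_adjusted[perm])
        assert (res_p.reject == res.reject[perm]).all()

    @pytest.mark.parametrize("bad", [[1.2], [-0.1], []])
    def test_invalid_pvalues_rejected(self, bad):
        with pytest.raises(ValueError):
            tsbh_adjust(bad)

    def test_global_null_false_discovery_controlled(self):
        # all-null replicates: FDR = P(any rejection) must stay near alpha
        rng = np.random.default_rng(20)
        false_disc = sum(
            tsbh_adjust(rng.uniform(size=20), alpha=0.05).reject.any() for _ in range(1000)
        )
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert false_disc / 1000 <= 0.05 + 3 * se


class TestEnrichmentReport:
    def test_expected_counts_proportional_to_sizes(self):
        table = PopulationTable.from_mapping(
            {
                **{f"a{k}": "A" for k in range(10)},
                **{f"b{k}": "B" for k in range(20)},
                **{f"c{k}": "C" for k in range(70)},
            }
        )
        rng = np.random.default_rng(6)
        partners = rng.choice(table.individuals, size=10, replace=False)
        segs = [make_segment(a="a0", b=p) for p in partners if p != "a0"]
        segs += [make_segment(a="a0", b="b0", chrom="2")] * (10 - len(segs))
        df = enrichment_report(segs, "a0", table)
        assert df["expected"].sum() == pytest.approx(df.attrs["T"], abs=1e-9)
        by_pop = df.set_index("population")["expected"]
        assert by_pop["A"] == pytest.approx(10 * df.attrs["T"] / 100)
        assert by_pop["C"] == pytest.approx(70 * df.attrs["T"] / 100)

    def test_observed_equal_expected_never_rejected(self):
        # equal-size populations, observed exactly at expectation everywhere
        table = PopulationTable.from_mapping(
            {f"p{i}_{k}": f"P{i}" for i in range(5) for k in range(10)}
        )
        # focal = p0_0 shares exactly one segment with each population
        segs = [make_segment(a="p0_0", b=f"p{i}_1") for i in range(1, 5)]
        segs.append(make_segment(a="p0_0", b="p0_1"))
        df = enrichment_report(segs, "p0_0", table)
        # each observed_i = 1 = n_i * T/N = 10*5/50; all upper tails >= 0.5
        assert (df["p_raw"] >= 0.5).all()
        assert not df["reject"].any()

    def test_zero_total_gives_unit_pvalues(self, focal_table):
        df = enrichment_report([], "F", focal_table)
        assert (df["p_raw"] == 1.0).all() and not df["reject"].any()
        assert df.attrs["T"] == 0

    def test_planted_population_most_often_rejected(self):
        config = lambda s: FocalStudyConfig(  # noqa: E731
            populations={f"P{i}": 40 for i in range(1, 11)},
            focal_population="P7",
            enrichment_factor=5.0,
            seed=s,
        )
        rejections: dict[str, int] = {}
        for seed in range(60):
            segs, focal, table, _, _ = simulate_focal_study(config(seed))
            df = enrichment_report(segs, focal, table)
            for pop in df.loc[df["reject"], "population"]:
                rejections[pop] = rejections.get(pop, 0) + 1
        assert max(rejections, key=rejections.get) == "P7"
        assert rejections["P7"] > 30  # majority of replicates
        null_rates = [rejections.get(f"P{i}", 0) / 60 for i in range(1, 11) if i != 7]
        assert max(null_rates) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)
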