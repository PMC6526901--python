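"""Gene-set enrichment, rank tests, ageing, and category summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import imprintsel as ims
from imprintsel.core_io import InputError
from imprintsel.genesets import GeneRecord, _percent


class TestOmegaRankTest:
    def test_identical_multisets_p_one(self):
        res = ims.omega_rank_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res["p_value"] == pytest.approx(1.0, abs=0.05)

    def test_matches_exact_permutation_enumeration(self):
        target, background = [10.0, 11.0, 12.0], [1.0, 2.0, 3.0]
        res = ims.omega_rank_test(target, background)
        # exact two-sided p by enumerating all 3-subsets of ranks
        pooled = sorted(target + background)
        obs_u = sum(
            sum(t > b for b in background) for t in target
        )
        n = 0
        extreme = 0
        for combo in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in combo]
            u = sum(
                sum(pooled[i] > pooled[j] for j in rest) for i in combo
            )
            n += 1
            if abs(u - 4.5) >= abs(obs_u - 4.5):
                extreme += 1
        assert res["p_value"] == pytest.approx(extreme / n, abs=0.02)

    def test_shifting_target_up_never_favors_target_lower(self):
        rng = np.random.default_rng(2)
        t = rng.normal(1.0, 0.3, 20)
        b = rng.normal(1.0, 0.3, 25)
        from scipy.stats import mannwhitneyu

        p_before = mannwhitneyu(t, b, alternative="less")[1]
        p_after = mannwhitneyu(t + 1.0, b, alternative="less")[1]
        assert p_after >= p_before

    def test_missing_values_excluded_and_empty_group_rejected(self):
        res = ims.omega_rank_test([0.1, None, np.nan], [0.5])
        assert res["n_target"] == 1
        with pytest.raises(InputError):
            ims.omega_rank_test([], [0.5])


class TestControlSets:
    def test_full_pool_single_set(self):
        pool = [f"g{i}" for i in range(100)]
        sets = ims.sample_control_sets(pool, set_size=100, n_sets=1, seed=0)
        assert sets == [sorted(pool, key=pool.index)]

    def test_same_seed_identical_sets(self):
        pool = [f"g{i}" for i in range(200)]
        a = ims.sample_control_sets(pool, 50, 5, seed=3)
        b = ims.sample_control_sets(pool, 50, 5, seed=3)
        assert a == b

    def test_eligibility_constraint_applied(self):
        pool = [f"g{i}" for i in range(50)]
        eligible = lambda g: int(g[1:]) % 2 == 0
        sets = ims.sample_control_sets(pool, 10, 4, eligible=eligible, seed=1)
        assert all(eligible(g) for s in sets for g in s)

    def test_inclusion_frequency_roughly_uniform(self):
        pool = [f"g{i}" for i in range(40)]
        sets = ims.sample_control_sets(pool, 10, 400, seed=7)
        freq = pd.Series([g for s in sets for g in s]).value_counts() / 400
        # expected inclusion probability 10/40 = 0.25
        assert freq.between(0.17, 0.33).all()

    def test_pool_too_small_rejected(self):
        with pytest.raises(InputError):
            ims.sample_control_sets(["a", "b"], set_size=5, n_sets=1)


def fisher_oracle(a, b, c, d):
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    return float(pmf[pmf <= hypergeom.pmf(a, n, r1, c1) * (1 + 1e-7)].sum())


class TestEnrichment:
    def test_equal_proportions_or_one(self):
        res = ims.ps_enrichment([True] * 5 + [False] * 5, [True] * 10 + [False] * 10)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_odds_ratio_arithmetic(self):
        res = ims.ps_enrichment(
            [True] * 6 + [False] * 26, [True] * 3 + [False] * 97
        )
        assert res.odds_ratio == pytest.approx(582 / 78)
        assert res.p_value == pytest.approx(fisher_oracle(6, 26, 3, 97), rel=1e-9)

    def test_zero_cell_haldane_correction_flagged(self):
        res = ims.ps_enrichment([True] * 4 + [False] * 6, [False] * 20)
        assert res.corrected
        assert np.isfinite(res.odds_ratio)

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            ims.ps_enrichment([], [True])

    def test_recovers_known_odds_ratio(self):
        # rates 0.5 vs 0.2 give true OR (0.5/0.5)/(0.2/0.8) = 4
        records, truth = ims.simulate_geneset(600, 600, 0.5, 0.2, seed=5)
        assert truth.expected["odds_ratio"] == pytest.approx(4.0)
        t = [r.ps_lineage for r in records if r.set_label == "target"]
        c = [r.ps_lineage for r in records if r.set_label == "control"]
        res = ims.ps_enrichment(t, c)
        assert 2.5 <= res.odds_ratio <= 6.5
        assert res.p_value < 1e-6

    def test_wgd_enrichment_against_background_totals(self):
        res = ims.wgd_enrichment([True] * 10 + [False] * 10, 100, 900)
        oracle = fisher_oracle(10, 10, 100, 900)
        assert res.p_value == pytest.approx(oracle, rel=1e-9)
        assert res.odds_ratio == pytest.approx((10 * 900) / (10 * 100))


class TestAgeClasses:
    def test_hits_only_in_focal_species_is_class_zero(self):
        assert ims.assign_age_class({0: 1e-30}) == 0

    def test_deep_hit_assigns_deep_class(self):
        assert ims.assign_age_class({0: 1e-40, 9: 1e-5}) == 9

    def test_cutoff_is_strict(self):
        # hit at exactly the cutoff is ignored
        assert ims.assign_age_class({0: 1e-50, 5: 1e-3, 2: 1e-8}) == 2

    def test_empty_table_rejected(self):
        with pytest.raises(InputError):
            ims.assign_age_class({})

    def test_dataframe_input(self):
        df = pd.DataFrame({"gene_id": ["g"] * 2, "clade_index": [0, 7],
                           "evalue": [1e-60, 1e-9]})
        assert ims.assign_age_class(df) == 7


class TestAgeDistributionTest:
    def test_identical_class_multisets_p_one(self):
        ages = [0, 1, 1, 3, 5, 9]
        assert ims.age_distribution_test(ages, ages) == pytest.approx(1.0)

    def test_two_class_reduction_matches_hypergeometric(self):
        a = [1] * 8 + [2] * 2
        b = [1] * 3 + [2] * 7
        p = ims.age_distribution_test(a, b)
        assert p == pytest.approx(fisher_oracle(8, 2, 3, 7), rel=1e-6)

    def test_class_relabelling_invariance(self):
        a = [0] * 5 + [3] * 5 + [7] * 3
        b = [0] * 2 + [3] * 8 + [7] * 4
        remap = {0: 7, 3: 0, 7: 3}
        p1 = ims.age_distribution_test(a, b)
        p2 = ims.age_distribution_test([remap[x] for x in a], [remap[x] for x in b])
        assert p2 == pytest.approx(p1, rel=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            ims.age_distribution_test([], [1])


class TestSummarizeCategories:
    @staticmethod
    def _records(n_lineage, n_site, n_both, n_none, label):
        recs = []
        i = 0
        for (lin, site), n in zip(
            [(True, False), (False, True), (True, True), (False, False)],
            [n_lineage, n_site, n_both, n_none],
        ):
            for _ in range(n):
                recs.append(GeneRecord(f"{label}{i}", label,
                                       ps_lineage=lin, ps_site=site))
                i += 1
        return recs

    def test_published_category_counts(self):
        # 30 iMEGs tested: 2 lineage-only, 7 site-only, 2 both;
        # 32 iPEGs tested: 4 lineage-only, 9 site-only, 6 both
        records = self._records(2, 7, 2, 19, "iMEG") + self._records(4, 9, 6, 13, "iPEG")
        table = ims.summarize_categories(records)
        assert table.loc["tested", "iPEG"] == 32
        assert table.loc["total_ps", "iPEG"] == 19
        assert table.loc["total_ps", "iPEG_pct"] == 59.4
        assert table.loc["total_ps", "Total"] == 30
        assert table.loc["total_ps", "Total_pct"] == 48.4
        assert table.loc["site_only", "Total_pct"] == 25.8
        assert table.loc["both", "Total_pct"] == 12.9

    def test_categories_partition_tested_genes(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(50):
            records.append(
                GeneRecord(f"g{i}", rng.choice(["iMEG", "iPEG"]),
                           ps_lineage=bool(rng.random() < 0.3),
                           ps_site=bool(rng.random() < 0.4))
            )
        table = ims.summarize_categories(records)
        for col in ("iMEG", "iPEG", "Total"):
            none = table.loc["tested", col] - (
                table.loc["lineage_only", col]
                + table.loc["site_only", col]
                + table.loc["both", col]
            )
            assert none >= 0
            assert table.loc["total_ps", col] == (
                table.loc["lineage_only", col]
                + table.loc["site_only", col]
                + table.loc["both", col]
            )

    def test_empty_input_all_zero(self):
        table = ims.summarize_categories([])
        assert (table.loc["tested", ["iMEG", "iPEG", "Total"]] == 0).all()

    def test_percent_rounding_half_up(self):
        assert _percent(1, 16) == 6.3  # 6.25 rounds up
        assert _percent(19, 32) == 59.4
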