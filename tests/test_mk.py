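"""McDonald-Kreitman counting, Fisher tests, and the statistic battery."""

import numpy as np
import pytest
from scipy.stats import hypergeom

import imprintsel as ims
from imprintsel.core_io import InputError
from imprintsel.mk import (
    ClassificationThresholds,
    MKCounts,
    aggregate_battery,
    classify_gene,
    count_mk,
    mk_fisher,
)


class TestCountMK:
    def test_synonymous_divergence(self):
        # population fixed for AAG, outgroup AAA: Lys/Lys, one DS
        c = count_mk(["AAG", "AAG"], "AAA")
        assert (c.DN, c.DS, c.PN, c.PS) == (0.0, 1.0, 0.0, 0.0)

    def test_nonsynonymous_polymorphism(self):
        # AAA (Lys) segregating with GAA (Glu): one PN
        c = count_mk(["AAA", "GAA"], "AAA")
        assert (c.DN, c.DS, c.PN, c.PS) == (0.0, 0.0, 1.0, 0.0)

    def test_population_identical_to_outgroup_all_zero(self):
        c = count_mk(["ATGAAA", "ATGAAA"], "ATGAAA")
        assert (c.DN, c.DS, c.PN, c.PS) == (0.0, 0.0, 0.0, 0.0)

    def test_polymorphic_site_not_double_counted_as_divergent(self):
        # site segregates A/G in the population while outgroup carries G:
        # counted as polymorphism only
        c = count_mk(["AAA", "AAG"], "AAG")
        assert c.PS == 1.0 and c.DS == 0.0 and c.DN == 0.0

    def test_frame_mismatch_rejected(self):
        with pytest.raises(InputError):
            count_mk(["AAAA", "AAAA"], "AAAA")

    def test_single_haplotype_rejected(self):
        with pytest.raises(InputError):
            count_mk(["AAA"], "AAA")

    def test_cell_exclusivity_on_simulated_population(self):
        haps, outgroup, truth = ims.simulate_population(120, 40, seed=9)
        c = count_mk(haps, outgroup)
        total_placed = sum(truth.expected.values())
        assert c.DN + c.DS + c.PN + c.PS == pytest.approx(total_placed, abs=0.51)
        for cell in ("DN", "DS", "PN", "PS"):
            assert getattr(c, cell) == pytest.approx(truth.expected[cell], abs=0.51)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestMKFisher:
    def test_matches_enumeration_oracle(self):
        p, flagged = mk_fisher(MKCounts("g", 10, 2, 2, 10))
        assert not flagged
        assert p == pytest.approx(fisher_oracle(10, 2, 2, 10), rel=1e-9)

    def test_balanced_table_p_one(self):
        p, _ = mk_fisher(MKCounts("g", 5, 5, 5, 5))
        assert p == pytest.approx(1.0)

    def test_all_zero_table_flagged(self):
        p, flagged = mk_fisher(MKCounts("g", 0, 0, 0, 0))
        assert p == 1.0 and flagged

    def test_fractional_counts_rounded_half_up(self):
        p_frac, _ = mk_fisher(MKCounts("g", 9.5, 2.4, 2.5, 9.4))
        p_int, _ = mk_fisher(MKCounts("g", 10, 2, 3, 9))
        assert p_frac == p_int


class TestBattery:
    def test_published_aggregate_counts(self):
        b = aggregate_battery([MKCounts("all", 4740, 4161, 1988, 1662)], efi=1.205)
        assert round(b.dnds, 3) == 1.139
        assert round(b.pnps, 3) == 1.196
        assert round(b.FI, 3) == 0.952
        assert round(b.alpha, 3) == -0.210
        assert b.DoS == pytest.approx(4740 / 8901 - 1988 / 3650, abs=1e-12)
        assert round(b.DoS, 4) == -0.0121

    def test_perfectly_neutral_single_gene(self):
        b = aggregate_battery([MKCounts("g", 1, 1, 1, 1)], efi=1.0)
        assert b.FI == 1.0
        assert b.DoS == 0.0
        assert b.NI_TG == 1.0
        assert b.alpha == 0.0

    def test_alpha_identity_holds(self):
        rng = np.random.default_rng(4)
        counts = [
            MKCounts(f"g{i}", *rng.integers(1, 30, size=4)) for i in range(12)
        ]
        b = aggregate_battery(counts)
        assert b.alpha == pytest.approx((b.FI - b.eFI) / b.eFI, rel=1e-12)

    def test_ni_tg_formula(self):
        counts = [MKCounts("a", 4, 2, 3, 5), MKCounts("b", 6, 1, 2, 2)]
        num = 2 * 3 / (5 + 2) + 1 * 2 / (2 + 1)
        den = 5 * 4 / (5 + 2) + 2 * 6 / (2 + 1)
        b = aggregate_battery(counts)
        assert b.NI_TG == pytest.approx(num / den, rel=1e-12)

    def test_undefined_fi_when_ds_zero(self):
        b = aggregate_battery([MKCounts("g", 3, 0, 2, 5)])
        assert b.FI is None
        assert "fi_missing" in b.notes

    def test_neutral_simulation_recovers_fi_near_one(self):
        # equal nonsyn/syn rate ratios in polymorphism and divergence; the
        # band is ~3 sigma of Monte-Carlo error at this reduced gene count
        # (the full-scale recovery check lives in the acceptance suite)
        counts = []
        for seed in range(40):
            haps, outgroup, _ = ims.simulate_population(
                100, 20, theta_syn=5, theta_nonsyn=10, div_syn=10, div_nonsyn=20,
                seed=seed,
            )
            counts.append(count_mk(haps, outgroup, gene=f"g{seed}"))
        b = aggregate_battery(counts)
        assert 0.73 <= b.FI <= 1.37

    def test_doubling_nonsyn_divergence_raises_fi(self):
        def batch(div_nonsyn):
            counts = [
                count_mk(
                    *ims.simulate_population(
                        100, 20, theta_syn=5, theta_nonsyn=5,
                        div_syn=10, div_nonsyn=div_nonsyn, seed=seed,
                    )[:2]
                )
                for seed in range(25)
            ]
            return aggregate_battery(counts).FI

        assert batch(20) > batch(10)


class TestClassification:
    def test_extreme_positive_quadrant(self):
        c = MKCounts("g", 20, 2, 2, 20)
        assert classify_gene(c) == "positive"

    def test_purifying_quadrant(self):
        assert classify_gene(MKCounts("g", 1, 20, 1, 20)) == "purifying"

    def test_neutral_when_ratios_match(self):
        assert classify_gene(MKCounts("g", 10, 10, 10, 10)) == "neutral"

    def test_pseudogenization_candidate(self):
        c = MKCounts("g", 30, 10, 28, 9)  # both ratios high, no DN excess
        assert classify_gene(c) == "pseudogenization-candidate"

    def test_undefined_ratio_unclassified(self):
        assert classify_gene(MKCounts("g", 3, 0, 1, 5)) == "unclassified"
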