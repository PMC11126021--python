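"""Closed-form probabilities and expected richness, with exact-rational oracles."""

import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from _strategies import haplotype_tables
from qsrare import (
    FlatSpec,
    all_singletons,
    expected_richness_with,
    expected_richness_without,
    flat_expected_richness_with,
    flat_expected_richness_without,
    flat_p_seen,
    make_table,
    p_seen_bootstrap,
    p_seen_fraction,
    richness_ratio,
    variance_of_proportion,
)

# Independent oracles: exact rational expectations for tiny tables.


def exact_richness_without(counts, m):
    """Sum of hypergeometric seen-probabilities in exact rational arithmetic."""
    N = sum(counts)
    total = Fraction(math.comb(N, m))
    return sum(
        1 - Fraction(math.comb(N - c, m), 1) / total if N - c >= m else Fraction(1)
        for c in counts
    )


def exact_richness_with(counts, m):
    """Sum of multinomial seen-probabilities in exact rational arithmetic."""
    N = sum(counts)
    return sum(1 - Fraction(N - c, N) ** m for c in counts)


class TestPSeen:
    def test_bootstrap_limit_is_0_6321(self):
        assert round(p_seen_bootstrap(math.inf), 4) == 0.6321
        assert round(1 - p_seen_bootstrap(math.inf), 4) == 0.3679

    def test_single_item_always_drawn(self):
        assert p_seen_bootstrap(1) == 1.0

    def test_two_items_by_hand(self):
        assert p_seen_bootstrap(2) == pytest.approx(0.75, abs=1e-15)

    def test_rejects_empty_sample(self):
        with pytest.raises(ValueError):
            p_seen_bootstrap(0)

    @pytest.mark.parametrize(
        "f, seen",
        [(0.1, 0.0952), (0.5, 0.3935), (1.0, 0.6321)],
    )
    def test_fraction_limits(self, f, seen):
        assert round(p_seen_fraction(f), 4) == seen

    def test_full_fraction_equals_bootstrap(self):
        assert p_seen_fraction(1.0) == p_seen_bootstrap(math.inf)
        assert p_seen_fraction(1.0, 500) == pytest.approx(p_seen_bootstrap(500), rel=1e-14)

    @pytest.mark.parametrize("f", [0.0, -0.1, 1.5])
    def test_fraction_domain(self, f):
        with pytest.raises(ValueError):
            p_seen_fraction(f)

    def test_monotone_in_fraction(self):
        vals = [p_seen_fraction(f / 100) for f in range(1, 101)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_finite_n_converges_to_limit(self):
        for f in (0.1, 0.5, 1.0):
            assert p_seen_fraction(f, 10**6) == pytest.approx(
                p_seen_fraction(f), abs=1e-6
            )


class TestFlatPSeen:
    def test_reduces_to_p_seen_fraction_at_k_1(self):
        for n in (10, 1000):
            for f in (0.25, 1.0):
                assert flat_p_seen(FlatSpec(n, 1, f)) == pytest.approx(
                    p_seen_fraction(f, n), rel=1e-14
                )

    def test_limit_flag(self):
        assert flat_p_seen(FlatSpec(1000, 3), limit=True) == pytest.approx(
            -math.expm1(-3), rel=1e-14
        )


class TestExpectedRichness:
    def test_full_draw_recovers_every_haplotype(self):
        t = make_table(["a", "b", "c"], [4, 2, 1])
        assert expected_richness_without(t, t.N) == pytest.approx(3.0, abs=1e-12)

    def test_empty_draw(self):
        t = make_table(["a"], [3])
        assert expected_richness_without(t, 0) == 0.0
        assert expected_richness_with(t, 0) == 0.0

    def test_all_singletons_rarefaction_is_exact(self):
        t = all_singletons(10_000)
        assert expected_richness_without(t, 1000) == pytest.approx(1000.0, abs=1e-9)

    def test_single_haplotype_with_replacement(self):
        t = make_table(["a"], [5])
        assert expected_richness_with(t, 3) == 1.0

    def test_rejects_m_above_n(self):
        t = make_table(["a"], [5])
        with pytest.raises(ValueError):
            expected_richness_without(t, 6)

    @pytest.mark.parametrize(
        "counts, m",
        [([2, 1], 2), ([5, 4, 3], 6), ([1, 1, 1, 1], 2), ([7, 1, 1], 4)],
    )
    def test_matches_exact_rational_oracle(self, counts, m):
        t = make_table([f"h{i}" for i in range(len(counts))], counts)
        assert expected_richness_without(t, m) == pytest.approx(
            float(exact_richness_without(counts, m)), rel=1e-12
        )
        assert expected_richness_with(t, m) == pytest.approx(
            float(exact_richness_with(counts, m)), rel=1e-12
        )

    @given(haplotype_tables(max_h=6, max_count=8), st.integers(0, 20))
    def test_property_matches_exact_oracle(self, t, m_raw):
        m = m_raw % (t.N + 1)
        counts = t.counts.tolist()
        assert expected_richness_without(t, m) == pytest.approx(
            float(exact_richness_without(counts, m)), rel=1e-12, abs=1e-12
        )
        assert expected_richness_with(t, m) == pytest.approx(
            float(exact_richness_with(counts, m)), rel=1e-12, abs=1e-12
        )

    def test_monotone_in_subsample_size(self):
        t = make_table(["a", "b", "c"], [10, 5, 1])
        wo = [expected_richness_without(t, m) for m in range(t.N + 1)]
        w = [expected_richness_with(t, m) for m in range(t.N + 1)]
        assert all(a < b for a, b in zip(wo, wo[1:]))
        assert all(a < b for a, b in zip(w, w[1:]))

    def test_flat_reduction_identity(self):
        """The general sum collapses to the flat-case formula exactly."""
        from qsrare import flat as flat_table

        for n, k, f in [(100, 3, 0.5), (50, 1, 0.2), (200, 5, 1.0)]:
            spec = FlatSpec(n, k, f)
            t = flat_table(n, k)
            assert flat_expected_richness_without(spec) == pytest.approx(
                expected_richness_without(t, spec.m), rel=1e-10
            )
            assert flat_expected_richness_with(spec) == pytest.approx(
                expected_richness_with(t, spec.m), rel=1e-10
            )

    def test_log_space_stays_finite_at_ten_million_reads(self):
        t = make_table(["big", "mid", "one"], [9_000_000, 999_999, 1])
        e = expected_richness_without(t, 1_000_000)
        assert math.isfinite(e)
        # P(the singleton is drawn) = m/N exactly; the other two are certain.
        assert e == pytest.approx(2 + 1_000_000 / 10_000_000, abs=1e-9)
        ew = expected_richness_with(t, 1_000_000)
        assert math.isfinite(ew) and 2.0 < ew < 3.0


class TestRichnessRatio:
    def test_bounded_by_one_on_grid(self):
        for k in range(1, 11):
            for f in [x / 10 for x in range(1, 11)]:
                assert 0.0 < richness_ratio(FlatSpec(10_000, k, f)) <= 1.0 + 1e-12

    def test_tends_to_one_for_abundant_haplotypes(self):
        assert richness_ratio(FlatSpec(10_000, 50, 0.5)) == pytest.approx(1.0, abs=1e-6)

    def test_pure_bootstrap_ratio_near_0_632(self):
        assert richness_ratio(FlatSpec(10_000, 1, 1.0)) == pytest.approx(
            1 - 1 / math.e, abs=1e-3
        )

    def test_empty_subsample_rejected(self):
        with pytest.raises(ValueError):
            richness_ratio(FlatSpec(10, 1, 0.01))


class TestVarianceOfProportion:
    def test_by_formula(self):
        assert variance_of_proportion(0.5, 100) == pytest.approx(0.0025)
        assert variance_of_proportion(0.0, 10) == 0.0
        assert variance_of_proportion(1.0, 10) == 0.0

    def test_prominent_master_stability(self):
        sd = math.sqrt(variance_of_proportion(0.49231, 100_000))
        assert sd == pytest.approx(0.00158, abs=1e-4)
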