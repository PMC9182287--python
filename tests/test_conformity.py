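import numpy as np
import pytest

from waterconform import (
    GuardBandRule,
    SpecificationLimits,
    acceptance_interval,
    assess,
    consumer_risk_analytic,
    consumer_risk_mc,
    decide,
    guard_band,
    risk_histogram,
    standard_uncertainty,
)

RULE = GuardBandRule()


class TestGuardBand:
    def test_from_fixture_scales(self):
        # Mn MADe route: s*=0.0248, p=72 -> g = 0.006 at 3 d.p.
        g = guard_band(standard_uncertainty(0.0248, 72), RULE)
        assert round(g, 3) == 0.006
        # pH nIQR route: s*=0.645, p=52 -> g = 0.18 at 2 d.p.
        assert round(guard_band(standard_uncertainty(0.645, 52), RULE), 2) == 0.18

    def test_zero_uncertainty(self):
        assert guard_band(0.0, RULE) == 0.0

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            GuardBandRule(alpha=0.7)
        with pytest.raises(ValueError):
            GuardBandRule(z=-1.0)


class TestAcceptanceInterval:
    def test_zero_guard_band_equals_tolerance(self):
        spec = SpecificationLimits(lower=6.0, upper=9.0)
        interval = acceptance_interval(spec, 0.0)
        assert (interval.lower, interval.upper) == (6.0, 9.0)

    def test_two_sided_shrinks_inward(self):
        interval = acceptance_interval(SpecificationLimits(lower=6.0, upper=9.0), 0.095)
        assert interval.lower == pytest.approx(6.095)
        assert interval.upper == pytest.approx(8.905)

    def test_one_sided_keeps_absent_side_absent(self):
        interval = acceptance_interval(SpecificationLimits(upper=0.1), 0.006)
        assert interval.lower is None
        assert interval.upper == pytest.approx(0.094)

    def test_collapsing_guard_band_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            acceptance_interval(SpecificationLimits(lower=6.0, upper=9.0), 1.6)


class TestDecide:
    def test_center_inside(self):
        interval = acceptance_interval(SpecificationLimits(lower=6.0, upper=9.0), 0.1)
        assert decide(6.20, interval) == "conform"

    def test_center_beyond_guarded_limit(self):
        interval = acceptance_interval(SpecificationLimits(upper=0.1), 0.006)
        assert decide(0.096, interval) == "not conform"

    def test_boundary_counts_as_conform(self):
        interval = acceptance_interval(SpecificationLimits(upper=5.0), 0.5)
        assert decide(4.50, interval) == "conform"

    def test_monotone_in_guard_band(self):
        # Growing g can only flip conform -> not conform, never back.
        spec = SpecificationLimits(lower=6.0, upper=9.0)
        center = 6.25
        previous = "conform"
        for g in np.linspace(0.0, 1.4, 30):
            verdict = decide(center, acceptance_interval(spec, g))
            assert not (previous == "not conform" and verdict == "conform")
            previous = verdict


class TestAnalyticRisk:
    def test_center_on_the_limit_is_half(self):
        assert consumer_risk_analytic(5.0, 0.3, SpecificationLimits(upper=5.0)) == pytest.approx(0.5)

    def test_vanishing_uncertainty_inside(self):
        assert consumer_risk_analytic(4.5, 1e-9, SpecificationLimits(upper=5.0)) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_u_zero(self):
        spec = SpecificationLimits(upper=5.0)
        assert consumer_risk_analytic(4.5, 0.0, spec) == 0.0
        assert consumer_risk_analytic(5.5, 0.0, spec) == 1.0

    def test_mn_fixture_inputs(self):
        # center 0.096, u = 1.25*0.0410/sqrt(72) against TU = 0.1
        u = standard_uncertainty(0.0410, 72)
        risk = consumer_risk_analytic(0.096, u, SpecificationLimits(upper=0.1))
        assert risk == pytest.approx(0.254, abs=1e-3)

    def test_center_outside_reports_mass_inside(self):
        spec = SpecificationLimits(upper=1000.0)
        risk = consumer_risk_analytic(1026.0, 17.59, spec)
        assert risk == pytest.approx(0.0697, abs=2e-3)

    def test_strictly_increasing_in_u_inside_one_sided(self):
        spec = SpecificationLimits(upper=5.0)
        risks = [consumer_risk_analytic(4.5, u, spec) for u in np.linspace(0.05, 2.0, 40)]
        assert all(b > a for a, b in zip(risks, risks[1:]))


class TestMonteCarloRisk:
    def test_reproducible_bit_for_bit(self):
        spec = SpecificationLimits(upper=5.0)
        a = consumer_risk_mc(4.5, 0.3, spec, n_draws=50_000, seed=11)
        b = consumer_risk_mc(4.5, 0.3, spec, n_draws=50_000, seed=11)
        assert a == b

    def test_seed_to_seed_scatter_within_sampling_error(self):
        spec = SpecificationLimits(upper=5.0)
        r = consumer_risk_analytic(4.5, 0.3, spec)
        bound = 4 * np.sqrt(r * (1 - r) / 50_000)
        a = consumer_risk_mc(4.5, 0.3, spec, n_draws=50_000, seed=1)
        b = consumer_risk_mc(4.5, 0.3, spec, n_draws=50_000, seed=2)
        assert abs(a - b) < 2 * bound

    def test_agrees_with_analytic_oracle_over_random_configs(self):
        # 50 random (center, u, spec) triples; MC within 4 standard errors.
        rng = np.random.default_rng(2022)
        n = 20_000
        for i in range(50):
            center = rng.uniform(-2, 2)
            u = rng.uniform(0.05, 1.5)
            kind = i % 3
            if kind == 0:
                spec = SpecificationLimits(upper=float(rng.uniform(0, 3)))
            elif kind == 1:
                spec = SpecificationLimits(lower=float(rng.uniform(-3, 0)))
            else:
                lo = float(rng.uniform(-3, 0))
                spec = SpecificationLimits(lower=lo, upper=lo + float(rng.uniform(0.5, 4)))
            analytic = consumer_risk_analytic(center, u, spec)
            mc = consumer_risk_mc(center, u, spec, n_draws=n, seed=int(rng.integers(2**31)))
            se = np.sqrt(max(analytic * (1 - analytic), 1e-12) / n)
            assert abs(mc - analytic) <= 4 * se + 1e-9

    def test_rejects_tiny_draw_counts(self):
        with pytest.raises(ValueError):
            consumer_risk_mc(4.5, 0.3, SpecificationLimits(upper=5.0), n_draws=10)


class TestRiskHistogram:
    def test_counts_conserved_and_risk_matches_mc(self):
        spec = SpecificationLimits(upper=5.0)
        hist = risk_histogram(4.5, 0.3, spec, n_draws=20_000, n_bins=40, seed=5)
        assert hist.counts.sum() == 20_000
        assert hist.risk == consumer_risk_mc(4.5, 0.3, spec, n_draws=20_000, seed=5)
        assert hist.au == pytest.approx(5.0 - 1.64 * 0.3)

    def test_ph_inputs_concentrate_inside_limits(self):
        spec = SpecificationLimits(lower=6.0, upper=9.0)
        u = standard_uncertainty(0.645, 52)
        hist = risk_histogram(6.20, u, spec, n_draws=50_000, n_bins=60, seed=9)
        draws_outside = hist.risk  # center inside -> risk == fraction outside
        assert draws_outside < 0.05
        inside = 1 - draws_outside
        assert inside > 0.95

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            risk_histogram(4.5, 0.3, SpecificationLimits(upper=5.0), n_bins=0)


class TestAssess:
    def test_ecoli_made_not_conform(self, macae, limits):
        decision = assess(macae["Ecoli"], limits["Ecoli"], "MADe", n_draws=20_000, seed=1)
        assert decision.verdict == "not conform"
        assert 0.0 < decision.consumer_risk < 0.10

    def test_bod_niqr_conform_with_small_risk(self, macae, limits):
        decision = assess(macae["BOD"], limits["BOD"], "nIQR", n_draws=20_000, seed=1)
        assert decision.verdict == "conform"
        assert decision.consumer_risk < 0.05

    def test_ph_sd_risk_negligible(self, macae, limits):
        decision = assess(macae["pH"], limits["pH"], "SD", n_draws=20_000, seed=1)
        assert decision.verdict == "conform"
        assert decision.consumer_risk < 1e-3

    def test_bod_sd_flagged_without_overlap(self, macae, limits):
        decision = assess(macae["BOD"], limits["BOD"], "SD", n_draws=20_000, seed=1)
        assert decision.without_overlap
        assert decision.verdict == "not conform"

    def test_unknown_approach_rejected(self, macae, limits):
        with pytest.raises(ValueError, match="unknown approach"):
            assess(macae["pH"], limits["pH"], "Huber")
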