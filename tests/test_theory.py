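"""Analytic phase diagram: threshold lines, classification, timing."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bottlepath as bp
from bottlepath.theory import single_mutant_end_exponent


class TestThresholdLines:
    def test_reference_values(self, landscape, delta):
        # direct evaluation of the line formulas at beta = 0.5
        assert bp.line1_alpha(0.5, landscape) == pytest.approx(5 / 3)
        assert bp.line2_alpha(delta) == pytest.approx(1.3)
        assert bp.line3_alpha(0.5, landscape, delta) == pytest.approx(107 / 70)
        assert bp.line4_alpha(landscape, delta) == pytest.approx(1.3 + 2 / 9)
        assert bp.line5_alpha(landscape, delta) == pytest.approx(1 + 0.26 / 0.35)

    def test_line1_meets_corner_as_beta_approaches_one(self, landscape):
        assert bp.line1_alpha(1 - 1e-9, landscape) == pytest.approx(1.0, abs=1e-6)

    def test_line1_equivalent_to_survival_exponent(self, landscape):
        # alpha above line (1) <=> end-of-cycle exponent (alpha-1) r10/r00
        # beats the dilution exponent (alpha-beta)
        for beta in (0.1, 0.5, 0.9):
            thresh = bp.line1_alpha(beta, landscape)
            for alpha in (thresh - 0.05, thresh + 0.05):
                z10 = (alpha - 1) * landscape.r10 / landscape.r00
                assert (z10 > alpha - beta) == (alpha > thresh)

    def test_line3_above_establishment_line(self, landscape, delta):
        for beta in np.linspace(0.05, 0.95, 19):
            assert bp.line3_alpha(beta, landscape, delta) > delta

    def test_line3_degenerates_to_line1(self):
        flat = bp.FitnessLandscape(r00=0.2, r10=0.35, r01=0.3500001, r11=1.0)
        l3 = bp.line3_alpha(0.4, flat, delta=1 + 1e-9)
        assert l3 == pytest.approx(bp.line1_alpha(0.4, flat), rel=1e-4)

    def test_line4_limit_fast_growing_strong_mutant(self, delta):
        steep = bp.FitnessLandscape(r00=0.2, r10=0.35, r01=500.0, r11=501.0)
        assert bp.line4_alpha(steep, delta) == pytest.approx(delta, abs=1e-3)

    def test_line5_limit_delta_to_one(self, landscape):
        assert bp.line5_alpha(landscape, 1 + 1e-9) == pytest.approx(
            1 + landscape.r00 / landscape.r10, abs=1e-6
        )

    def test_line5_above_line4_for_reference_set(self, landscape, delta):
        assert bp.line5_alpha(landscape, delta) > bp.line4_alpha(landscape, delta)

    def test_degenerate_landscape_rejected(self, landscape):
        with pytest.raises(bp.ParameterError):
            bp.line1_alpha(1.5, landscape)  # outside 0 < beta < 1


class TestClassify:
    def test_northeast_all_survive(self, landscape, delta):
        config = bp.classify(0.5, 3.0, landscape, delta)
        assert config.label == "all_survive"
        assert config.transitions == frozenset(
            {("00", "10"), ("00", "01"), ("10", "11"), ("01", "11")}
        )
        assert config.status == {"10": "survives", "01": "survives", "11": "survives"}

    def test_southwest_below_delta_only10(self, landscape, delta):
        config = bp.classify(0.1, 1.05, landscape, delta)
        assert config.label == "only10"
        assert config.transitions == frozenset({("00", "10")})
        assert config.status == {
            "10": "establishes_each_cycle",
            "01": "absent",
            "11": "absent",
        }

    def test_strong_mutation_inaccessible_below_delta(self, landscape, delta):
        for beta in (0.1, 0.5, 0.9):
            for alpha in (1.05, 1.15, 1.25):
                config = bp.classify(beta, alpha, landscape, delta)
                assert ("00", "01") not in config.transitions
                assert ("01", "11") not in config.transitions
                assert config.status["01"] == "absent"

    def test_boundary_point_assigned_above(self, landscape, delta):
        beta = 0.5
        on_line = bp.classify(beta, bp.line1_alpha(beta, landscape), landscape, delta)
        assert on_line.status["10"] == "survives"
        on_two = bp.classify(beta, delta, landscape, delta)
        assert on_two.status["01"] != "absent"

    def test_six_labels_on_dense_grid_all_contain_first_transition(
        self, landscape, delta
    ):
        labels = set()
        for beta in np.linspace(0.05, 0.95, 60):
            for alpha in np.linspace(1.05, 3.0, 60):
                config = bp.classify(beta, alpha, landscape, delta)
                labels.add(config.label)
                assert ("00", "10") in config.transitions
        assert labels == set(bp.LABELS)

    def test_four_corner_zones(self, landscape, delta):
        corners = {
            bp.corner(beta, alpha, landscape, delta)
            for beta in np.linspace(0.05, 0.95, 40)
            for alpha in np.linspace(1.05, 3.0, 40)
        }
        assert corners == {"SW", "SE", "NW", "NE"}

    def test_northwest_gains_second_route_above_line5(self, landscape, delta):
        # beta=0.1: line3=1.643, line1=2.2; line5=1.743 sits inside the NW corner
        below = bp.classify(0.1, 1.70, landscape, delta)
        above = bp.classify(0.1, 1.80, landscape, delta)
        assert below.label == above.label == "01survives_11from01"
        assert ("10", "11") not in below.transitions
        assert ("10", "11") in above.transitions

    def test_sw_above_line4_double_mutant_establishes(self, landscape, delta):
        # small beta, alpha between line (4) and the survival lines
        config = bp.classify(0.05, 1.60, landscape, delta)
        assert config.label == "10and01_no_survival"
        assert config.status["11"] == "establishes_each_cycle"
        assert ("01", "11") in config.transitions

    @given(beta=st.floats(0.05, 0.95), alpha=st.floats(1.05, 3.0))
    def test_status_transition_consistency(self, beta, alpha):
        landscape = bp.FitnessLandscape(0.2, 0.35, 0.9, 1.0)
        config = bp.classify(beta, alpha, landscape, 1.3)
        if ("10", "11") in config.transitions:
            assert config.status["10"] != "absent"
        if ("01", "11") in config.transitions:
            assert config.status["01"] != "absent"
        if config.status["11"] != "absent":
            assert (("10", "11") in config.transitions) or (
                ("01", "11") in config.transitions
            )


class TestEstablishmentCycle:
    def test_first_cycle_above_lines_four_and_five(self, landscape, delta):
        line4 = bp.line4_alpha(landscape, delta)
        for beta in (0.1, 0.5, 0.9):
            forecast = bp.predict_establishment_cycle(beta, line4 + 0.01, landscape, delta)
            assert forecast.k11 == 1
            assert forecast.route == "from01"

    def test_southwest_never(self, landscape, delta):
        forecast = bp.predict_establishment_cycle(0.1, 1.05, landscape, delta)
        assert math.isinf(forecast.k11)
        assert forecast.route is None

    def test_multi_cycle_recursion_southeast(self, landscape, delta):
        # (0.8, 1.35): 10 survives (line1 = 1.267), 01 establishes only;
        # exponent recursion: 0.6125 + 0.4125 (k-1) >= 1.3 => k = 3
        forecast = bp.predict_establishment_cycle(0.8, 1.35, landscape, delta)
        assert forecast.k11 == 3
        assert forecast.route == "from10"
        e2 = single_mutant_end_exponent("10", 2, 0.8, 1.35, landscape, delta)
        e3 = single_mutant_end_exponent("10", 3, 0.8, 1.35, landscape, delta)
        assert e2 < delta <= e3

    def test_horizon_reports_infinity(self, landscape, delta):
        # blue zone point needing more than 7 cycles
        unbounded = bp.predict_establishment_cycle(0.92, 1.135, landscape, delta, None)
        assert 7 < unbounded.k11 < math.inf
        capped = bp.predict_establishment_cycle(0.92, 1.135, landscape, delta, 7)
        assert math.isinf(capped.k11)

    def test_k11_monotone_in_alpha(self, landscape, delta):
        for beta in (0.2, 0.5, 0.8):
            ks = [
                bp.predict_establishment_cycle(beta, a, landscape, delta, None).k11
                for a in np.linspace(1.05, 3.0, 80)
            ]
            assert all(k2 <= k1 for k1, k2 in zip(ks, ks[1:]))

    def test_consistency_with_classify(self, landscape, delta):
        for beta in np.linspace(0.05, 0.95, 25):
            for alpha in np.linspace(1.05, 3.0, 25):
                forecast = bp.predict_establishment_cycle(beta, alpha, landscape, delta, None)
                absent = forecast.config.status["11"] == "absent"
                assert absent == math.isinf(forecast.k11)


class TestDesignHelpers:
    def test_optimal_beta_reference_value(self, landscape):
        beta_star = bp.optimal_beta(1.4, landscape)
        assert beta_star.beta == pytest.approx(0.7)
        assert not beta_star.clipped

    def test_optimal_beta_sits_on_line1(self, landscape):
        for alpha in (1.2, 1.35, 1.5):
            beta_star = bp.optimal_beta(alpha, landscape).beta
            assert bp.line1_alpha(beta_star, landscape) == pytest.approx(alpha)

    def test_optimal_beta_clipped_outside_domain(self, landscape):
        assert bp.optimal_beta(2.5, landscape).clipped

    def test_optimal_beta_is_grid_argmin_of_k11(self, landscape, delta):
        # alpha below min(line4, line5) and below line (3) everywhere, so the
        # double mutant can only come through the 10 background
        alpha = 1.35
        betas = np.linspace(0.05, 0.95, 181)
        ks = np.array(
            [bp.predict_establishment_cycle(b, alpha, landscape, delta, None).k11 for b in betas]
        )
        beta_star = bp.optimal_beta(alpha, landscape).beta
        nearest = int(np.argmin(np.abs(betas - beta_star)))
        assert ks[nearest] == ks.min()

    def test_k11_unimodal_in_beta(self, landscape, delta):
        alpha = 1.35
        betas = np.linspace(0.05, 0.95, 90)
        ks = [bp.predict_establishment_cycle(b, alpha, landscape, delta, None).k11 for b in betas]
        beta_star = bp.optimal_beta(alpha, landscape).beta
        left = [k for b, k in zip(betas, ks) if b < beta_star - 1e-9]
        right = [k for b, k in zip(betas, ks) if b > beta_star + 1e-9]
        assert all(math.isinf(k) for k in left)  # bottleneck too severe
        assert all(k2 >= k1 for k1, k2 in zip(right, right[1:]))  # shorter cycles slow it

    def test_recommended_dilution_matches_dilution_at_optimal_beta(self, landscape):
        n, alpha = 1e8, 1.5
        beta_star = bp.optimal_beta(alpha, landscape).beta
        expected = bp.DemographyParams(n=n, beta=beta_star, alpha=alpha, delta=1.3).D_n
        assert bp.recommended_dilution(alpha, landscape, n) == pytest.approx(expected)

    def test_recommended_dilution_worked_design_example(self, landscape):
        # 10 mL saturating at 1e9/mL with mutation rate 1e-7: n = 1e7,
        # final size 1e10 => alpha = 10/7 and dilution (1e-3)**(r10/r00)
        value = bp.recommended_dilution(10 / 7, landscape, 1e7)
        assert value == pytest.approx((1e-3) ** (0.35 / 0.2))

    def test_no_dilution_needed_as_alpha_approaches_one(self, landscape):
        assert bp.recommended_dilution(1 + 1e-12, landscape, 1e9) == pytest.approx(1.0)
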