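"""Landscape geometry: gradients, global optimum, jump directions."""

import numpy as np
import pandas as pd
import pytest

import fitscape as fs
from fitscape.geometry import DEFAULT_DOMAIN

PARAMS = fs.LandscapeParameters(vmax=2, eh=20, ft=0.3, cost_flha=0.002,
                                cost_fgha=0.004, cost_copy=0.01)


def finite_difference_gradient(point, params, p_ref, h=1e-6):
    e_a, e_g = point
    def w(a, g):
        return fs.landscape_fitness(a, g, p_ref, params, clamp=False)
    return np.array([
        (w(e_a + h, e_g) - w(e_a - h, e_g)) / (2 * h),
        (w(e_a, e_g + h) - w(e_a, e_g - h)) / (2 * h),
    ])


class TestGradient:
    def test_fgha_component_is_minus_cost_everywhere(self, rng):
        for _ in range(10):
            pt = rng.uniform(5, 300, 2)
            g = fs.gradient_at(pt, PARAMS, 9.0)
            assert g[1] == pytest.approx(-PARAMS.cost_fgha)

    def test_stationary_at_optimal_flha(self):
        e_star = fs.optimal_flha(PARAMS)
        g = fs.gradient_at((e_star, 50.0), PARAMS, 9.0)
        assert g[0] == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_central_differences_on_random_points(self, rng):
        for _ in range(100):
            pt = rng.uniform(10, 300, 2)
            ana = fs.gradient_at(pt, PARAMS, 9.0)
            num = finite_difference_gradient(pt, PARAMS, 9.0)
            assert np.allclose(ana, num, rtol=1e-6, atol=1e-9)

    def test_clamped_region_warns_and_zeroes_benefit(self):
        p = fs.LandscapeParameters(vmax=2, eh=20, ft=1.5, cost_flha=0.002,
                                   cost_fgha=0.004)
        with pytest.warns(UserWarning, match="clamped"):
            g = fs.gradient_at((1.0, 50.0), p, 9.0)
        assert g[0] == pytest.approx(-p.cost_flha)


class TestGlobalOptimum:
    def test_flha_matches_closed_form_when_interior(self):
        rep = fs.global_optimum(PARAMS, ((1, 150), (1, 150)), 9.0)
        # closed form 121.42 lies inside [1, 150]
        assert rep.point[0] == pytest.approx(fs.optimal_flha(PARAMS),
                                             abs=1e-4)
        assert not rep.flha_on_boundary

    def test_fgha_always_at_lower_bound(self):
        rep = fs.global_optimum(PARAMS, ((1, 150), (2, 150)), 9.0)
        assert rep.point[1] == 2.0
        assert rep.fgha_on_boundary
        rep2 = fs.global_optimum(PARAMS, ((1, 150), (4, 150)), 9.0)
        assert rep2.point[1] == 4.0

    def test_large_cost_pushes_flha_to_lower_bound(self):
        p = fs.LandscapeParameters(vmax=1, eh=100, ft=0.0, cost_flha=10.0,
                                   cost_fgha=0.004)
        rep = fs.global_optimum(p, ((1, 150), (1, 150)), 9.0)
        assert rep.point[0] == 1.0
        assert rep.flha_on_boundary

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError):
            fs.global_optimum(PARAMS, ((10, 5), (1, 150)), 9.0)


class TestDirectionReport:
    def test_mutant_at_optimum_has_zero_angle_to_optimum(self):
        opt = fs.global_optimum(PARAMS, DEFAULT_DOMAIN, 9.0).point
        rep = fs.direction_report((100, 100), opt, PARAMS,
                                  DEFAULT_DOMAIN, 9.0, mutation_id="m")
        assert rep.angle_to_optimum == pytest.approx(0.0, abs=1e-4)
        assert rep.nearest_reference == "optimum"

    def test_proportional_halving_is_on_the_diagonal(self):
        rep = fs.direction_report((100, 100), (50, 50), PARAMS,
                                  DEFAULT_DOMAIN, 9.0)
        assert rep.angle_to_diagonal == pytest.approx(0.0, abs=1e-4)
        assert rep.nearest_reference == "diagonal"

    def test_mutant_along_gradient_is_nearest_gradient(self):
        anc = np.array([100.0, 100.0])
        grad = fs.gradient_at(anc, PARAMS, 9.0)
        mut = anc + 30 * grad / np.linalg.norm(grad)
        rep = fs.direction_report(anc, mut, PARAMS, DEFAULT_DOMAIN, 9.0)
        assert rep.angle_to_gradient == pytest.approx(0.0, abs=1e-6)
        assert rep.nearest_reference == "gradient"

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError, match="displacement"):
            fs.direction_report((100, 100), (100, 100), PARAMS,
                                DEFAULT_DOMAIN, 9.0)

    def test_angles_in_range_and_nearest_is_argmin(self):
        rep = fs.direction_report((100, 100), (40, 10), PARAMS,
                                  DEFAULT_DOMAIN, 9.0)
        angles = {"gradient": rep.angle_to_gradient,
                  "optimum": rep.angle_to_optimum,
                  "diagonal": rep.angle_to_diagonal}
        assert all(0 <= a <= 180 for a in angles.values())
        assert rep.nearest_reference == min(angles, key=angles.get)

    def test_diagonal_and_optimum_angles_scale_invariant(self):
        # uniform rescaling of both axes (mU <-> relative scale) must not
        # change the diagonal/optimum angles; the gradient is covariant
        k = 3.7
        p_scaled = fs.LandscapeParameters(
            vmax=PARAMS.vmax, eh=PARAMS.eh * k, ft=PARAMS.ft,
            cost_flha=PARAMS.cost_flha / k, cost_fgha=PARAMS.cost_fgha / k,
            cost_copy=PARAMS.cost_copy)
        dom_scaled = tuple((lo * k, hi * k) for lo, hi in DEFAULT_DOMAIN)
        a = fs.direction_report((100, 100), (40, 10), PARAMS,
                                DEFAULT_DOMAIN, 9.0)
        b = fs.direction_report((100 * k, 100 * k), (40 * k, 10 * k),
                                p_scaled, dom_scaled, 9.0)
        assert b.angle_to_diagonal == pytest.approx(a.angle_to_diagonal,
                                                    abs=1e-6)
        assert b.angle_to_optimum == pytest.approx(a.angle_to_optimum,
                                                   abs=1e-4)
        assert b.angle_to_gradient == pytest.approx(a.angle_to_gradient,
                                                    abs=1e-6)

    def test_synthetic_jumps_near_optimum_prefer_optimum_over_gradient(
            self, clean_study, clean_fit):
        # the study's mutations jump toward low expression near the
        # optimum; with vanishing noise every one is closer to the
        # optimum vector than to the local gradient
        anc = clean_study[clean_study["category"] == "ancestor"].iloc[0]
        singles = clean_study[clean_study["category"].isin(
            ["single_A", "single_B"])]
        p = clean_fit.parameters
        dom = ((1.0, 300.0), (1.0, 300.0))
        closer = []
        for _, row in singles.iterrows():
            rep = fs.direction_report(
                (anc["flha_obs"], anc["fgha_obs"]),
                (row["flha_obs"], row["fgha_obs"]), p, dom,
                anc["copy_obs"], mutation_id=row["strain"])
            closer.append(rep.angle_to_optimum < rep.angle_to_gradient)
        assert all(closer)


class TestFlankAnalysis:
    def make_strains(self, levels, e_g=10.0, p=9.0):
        return pd.DataFrame({
            "strain": [f"s{i}" for i in range(len(levels))],
            "flha_obs": levels, "fgha_obs": e_g, "copy_obs": p,
        })

    def test_at_optimum_has_maximal_margin_among_non_overshooting(self):
        probe = fs.flank_analysis(self.make_strains([100.0]), PARAMS, "flha")
        x_opt = probe.iloc[0]["axis_optimum"]
        # margin = expression drop tolerated before W < 1; among strains
        # at or below the optimum it is largest at the optimum itself
        out = fs.flank_analysis(self.make_strains([x_opt, 40.0, 25.0]),
                                PARAMS, "flha")
        assert out.iloc[0]["side_of_optimum"] == "at optimum"
        assert out.iloc[0]["margin_to_cliff"] == out["margin_to_cliff"].max()

    def test_equal_fitness_opposite_flanks_low_side_has_smaller_margin(self):
        from scipy.optimize import brentq
        res = fs.flank_analysis(self.make_strains([100.0]), PARAMS, "flha")
        x_opt = res.iloc[0]["axis_optimum"]

        def w(x):
            return fs.landscape_fitness(x, 10.0, 9.0, PARAMS)
        target = w(x_opt) - 0.05
        lo = brentq(lambda x: w(x) - target, 1e-6, x_opt)
        hi = brentq(lambda x: w(x) - target, x_opt, 1e4)
        out = fs.flank_analysis(self.make_strains([lo, hi]), PARAMS, "flha")
        assert out.iloc[0]["side_of_optimum"] == "below"
        assert out.iloc[1]["side_of_optimum"] == "above"
        assert out.iloc[0]["fitness"] == pytest.approx(out.iloc[1]["fitness"])
        assert out.iloc[0]["margin_to_cliff"] < out.iloc[1]["margin_to_cliff"]

    def test_clamped_region_strain_has_nonpositive_margin(self):
        out = fs.flank_analysis(self.make_strains([2.0]), PARAMS, "flha")
        assert out.iloc[0]["fitness"] < 1.0
        assert out.iloc[0]["margin_to_cliff"] <= 0
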