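"""Tip-advance dynamics: noise, guidance, growth cycles, interactions."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from filoguide import (Grating, GuidanceParams, Population, SimParams,
                       grow_neurite, initial_direction, run_population,
                       simulate_swallowtail, step_tip)
from filoguide.simulate import (InteractionSettings, _guidance_from_u,
                                guidance_term, neurite_rngs,
                                trajectories_frame)

FLAT = Grating(0.5, 0.5, 0.0)


class TestInitialDirection:
    def test_truncation_contract(self, sim_params):
        p = replace(sim_params, laplace_interval=(-30.0, 30.0),
                    laplace_scale=40.0)
        rng = np.random.default_rng(0)
        draws = np.array([initial_direction(rng, p) for _ in range(100_000)])
        assert draws.min() > -30.0 and draws.max() < 30.0

    def test_zero_scale_degenerates_to_axis(self, sim_params):
        p = replace(sim_params, laplace_scale=0.0)
        rng = np.random.default_rng(0)
        assert all(initial_direction(rng, p) == 0.0 for _ in range(100))

    def test_distribution_matches_inverse_cdf_oracle(self, sim_params):
        """KS distance to the truncated-Laplace CDF below 0.01."""
        b, hi = 22.0, 30.0
        p = replace(sim_params, laplace_scale=b, laplace_interval=(-hi, hi))
        rng = np.random.default_rng(7)
        draws = np.array([initial_direction(rng, p) for _ in range(100_000)])

        def cdf(x):
            x = np.asarray(x, dtype=float)
            raw = np.where(x < 0, 0.5 * np.exp(x / b),
                           1.0 - 0.5 * np.exp(-x / b))
            lo_m, hi_m = 0.5 * math.exp(-hi / b), 1.0 - 0.5 * math.exp(-hi / b)
            return (raw - lo_m) / (hi_m - lo_m)

        ks = stats.kstest(draws, cdf).statistic
        assert ks < 0.01


class TestGuidanceTerm:
    def test_flat_substrate_contributes_nothing(self, sim_params):
        rng = np.random.default_rng(0)
        g = guidance_term(17.0, (0.0, 0.3), FLAT, sim_params, rng)
        assert g == 0.0

    def test_case1_uses_one_of_the_two_candidates(self, period1, sim_params):
        from filoguide import GrowthConeDisk, classify_contact
        tip = (0.0, 0.75)  # groove midpoint: symmetric case 1
        info = classify_contact(GrowthConeDisk(tip), period1)
        lam = (1 - math.exp(-sim_params.guidance.epsilon * 0.5)) * \
            (1 - math.exp(-sim_params.guidance.xi * sim_params.dt))
        g_lo = _guidance_from_u(0.0, tip, period1, sim_params, 0.2)
        g_hi = _guidance_from_u(0.0, tip, period1, sim_params, 0.8)
        assert g_lo == pytest.approx(lam * info.candidates[0])
        assert g_hi == pytest.approx(lam * info.candidates[1])

    def test_mirror_reflection_negates_term(self, sim_params):
        """Antithetically coupled draws: the reflected configuration turns
        by the exact opposite angle (1000 random configurations)."""
        rng = np.random.default_rng(42)
        g = Grating(0.5, 0.5, 0.25, phase_offset=0.0)
        # mirror of the band pattern across y = 0 is the pattern with
        # phase offset -ridge_width
        g_mirror = Grating(0.5, 0.5, 0.25, phase_offset=-0.5)
        for _ in range(1000):
            y = float(rng.uniform(-3, 3))
            theta = float(rng.uniform(-60, 60))
            u = float(rng.uniform(0, 1))
            if abs(u - 0.5) < 1e-6 or abs(y % 0.5 - 0.25) < 1e-9:
                continue  # exact symmetric choice points
            a = _guidance_from_u(theta, (0.0, y), g, sim_params, u)
            b = _guidance_from_u(-theta, (0.0, -y), g_mirror, sim_params,
                                 1.0 - u)
            assert b == pytest.approx(-a, abs=1e-12)


class TestStepTip:
    def test_noiseless_flat_straight_continuation(self, sim_params):
        p = replace(sim_params, sigma_omega=0.0)
        n = grow_neurite((0.0, 0.3), FLAT, p, duration=1.0)
        pts = n.path_points()
        # all headings identical: the path is a straight line
        seg = np.diff(pts, axis=0)
        angles = np.degrees(np.arctan2(seg[:, 1], seg[:, 0]))
        assert np.ptp(angles) < 1e-9

    def test_step_magnitude_is_speed_times_dt(self, period1, sim_params):
        n = grow_neurite((0.0, 0.3), period1, sim_params, duration=0.2)
        pts = n.path_points()
        steps = np.hypot(*np.diff(pts[1:], axis=0).T)
        np.testing.assert_allclose(
            steps, sim_params.v_ext * sim_params.dt, rtol=1e-12)

    def test_guided_heading_contracts_toward_axis(self, period1, sim_params):
        p = replace(sim_params, sigma_omega=0.0)
        rng = np.random.default_rng(0)
        from filoguide.simulate import Neurite
        start = np.array([0.0, 0.25])
        n = Neurite(soma=(0.0, 0.25), rng=rng,
                    points=[start, start + np.array([1.0, 0.6])],
                    heading_deg=30.0, target_length=1e9, length=1.0)
        step_tip(n, period1, p, rng)
        assert abs(n.heading_deg) <= 30.0

    def test_fixed_seed_bit_identical_trajectories(self, period1):
        runs = []
        for _ in range(2):
            p = SimParams(seed=9)
            n = grow_neurite((0.0, 0.3), period1, p, duration=6.0,
                             rng=neurite_rngs(9, 1)[0])
            runs.append(trajectories_frame([n]).to_csv(index=False))
        assert runs[0] == runs[1]


class TestGrowthCycles:
    def test_quarter_hour_pure_extension_adds_five_microns(self, period1,
                                                           sim_params):
        p = replace(sim_params, target_mean=1000.0, target_sd=0.0)
        n = grow_neurite((0.0, 0.3), period1, p, duration=0.25)
        assert n.length == pytest.approx(p.initial_length + 5.0, abs=1e-9)

    def test_target_length_distribution(self, sim_params):
        from filoguide.simulate import Neurite, _draw_target
        rng = np.random.default_rng(3)
        n = Neurite(soma=(0, 0), rng=rng, points=[np.zeros(2), np.ones(2)],
                    heading_deg=0.0, target_length=0.0)
        draws = np.array([_draw_target(n, sim_params) for _ in range(10_000)])
        se = 2.65 / math.sqrt(draws.size)
        assert abs(draws.mean() - 18.98) < 3 * se
        assert abs(draws.std() - 2.65) < 0.1

    def test_zero_retraction_speed_never_shrinks(self, period1, sim_params):
        p = replace(sim_params, v_ret=0.0)
        n = grow_neurite((0.0, 0.3), period1, p, duration=6.0)
        assert n.length >= p.initial_length - 1e-9

    def test_path_length_bookkeeping(self, period1, sim_params):
        n = grow_neurite((0.0, 0.3), period1, sim_params, duration=24.0)
        seg = np.diff(n.path_points(), axis=0)
        recomputed = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        assert abs(recomputed - n.length) < 1e-9

    def test_flat_null_heading_is_gaussian_random_walk(self, sim_params):
        """Heading increment variance matches sigma_omega**2 within 5%."""
        p = replace(sim_params, sigma_omega=5.0, target_mean=1e9,
                    target_sd=0.0)
        n = grow_neurite((0.0, 0.3), FLAT, p, duration=500.0,
                         rng=np.random.default_rng(11))
        pts = n.path_points()
        seg = np.diff(pts, axis=0)
        headings = np.unwrap(
            np.degrees(np.arctan2(seg[:, 1], seg[:, 0])), period=360.0)
        incr = np.diff(headings)
        assert abs(np.var(incr) / p.sigma_omega**2 - 1.0) < 0.05


class TestPopulation:
    def test_disabled_interactions_match_independent_runs(self, period1,
                                                          sim_params):
        pop = Population(somata=[(0.0, 0.2), (40.0, 3.7)])
        run_population(pop, period1, sim_params, duration=3.0)
        rngs = neurite_rngs(sim_params.seed, 2)
        for neu, soma, rng in zip(pop.neurites, pop.somata, rngs):
            solo = grow_neurite(soma, period1, sim_params, duration=3.0,
                                rng=rng)
            np.testing.assert_array_equal(neu.path_points(),
                                          solo.path_points())

    def test_repulsion_enforces_contact_distance(self, period1, sim_params):
        inter = InteractionSettings(repulsion=True, contact_distance=1.0)
        pop = Population(somata=[(0.0, 0.2), (0.0, 0.9)], interactions=inter)
        run_population(pop, period1, sim_params, duration=2.0)
        a, b = pop.neurites
        hist_a = np.array([(x, y) for _, x, y, _ in a.history])
        hist_b = np.array([(x, y) for _, x, y, _ in b.history])
        m = min(len(hist_a), len(hist_b))
        d = np.hypot(*(hist_a[:m] - hist_b[:m]).T)
        assert d.min() >= inter.contact_distance - 1e-9

    def test_attraction_draws_parallel_neighbours_together(self, period1,
                                                           sim_params):
        def terminal_gap(attract: bool) -> float:
            inter = InteractionSettings(attraction=attract,
                                        attraction_range=6.0,
                                        attraction_strength=0.5)
            pop = Population(somata=[(0.0, 0.0), (0.0, 4.0)],
                             interactions=inter)
            run_population(pop, period1, replace(sim_params, sigma_omega=0.0),
                           duration=1.0)
            a, b = pop.neurites
            return float(np.hypot(*(a.tip - b.tip)))

        assert terminal_gap(True) <= terminal_gap(False) + 1e-9

    def test_empty_population_rejected(self, period1, sim_params):
        with pytest.raises(ValueError):
            run_population(Population(somata=[]), period1, sim_params, 1.0)


class TestSwallowtailAssay:
    def test_tiny_tail_angle_turns_nearly_all(self, sim_params):
        res = simulate_swallowtail(100, 1.0, sim_params, duration=12.0)
        assert res["n_reached"] > 80
        assert res.turning_fraction > 0.93

    def test_stalled_axons_stop_near_the_corner(self, sim_params):
        res = simulate_swallowtail(150, 70.0, sim_params, duration=12.0)
        stalled = [o for o in res.outcomes if o.reached and not o.turned]
        assert stalled, "some axons should fail to turn at a steep tail"
        for o in stalled:
            # within one growth-cone radius of the branch boundary line
            assert o.final_position[0] <= 1.14

    def test_zero_cells_signalled(self, sim_params):
        with pytest.raises(ValueError):
            simulate_swallowtail(0, 40.0, sim_params)


def test_alignment_distribution_stable_over_time(sim_params):
    """Angular histograms at 12, 36 and 60 h differ by < 10 points per bin."""
    from filoguide.metrics import angular_histogram
    from filoguide.workbench import PERIOD1, run_cohort
    table, _ = run_cohort(150, PERIOD1, sim_params, 60.0, (12.0, 36.0, 60.0))
    hists = {}
    for t in (12.0, 36.0, 60.0):
        angles = table[np.isclose(table.t_h, t)].alignment_deg.to_numpy()
        hists[t] = angular_histogram(angles, 10.0)
    for t in (36.0, 60.0):
        assert np.max(np.abs(hists[t] - hists[12.0])) < 10.0


def test_guidance_concentrates_alignment_relative_to_flat(sim_params):
    """On the period-1 grating the near-axis 10-degree bin holds more mass
    than on a flat substrate (same cohort size and seeds)."""
    from filoguide.workbench import PERIOD1, run_cohort
    masses = {}
    for name, surf in (("grating", PERIOD1), ("flat", FLAT)):
        table, _ = run_cohort(200, surf, sim_params, 12.0, (12.0,))
        a = table[np.isclose(table.t_h, 12.0)].alignment_deg.to_numpy()
        masses[name] = (a < 10.0).mean()
    assert masses["grating"] > masses["flat"]
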