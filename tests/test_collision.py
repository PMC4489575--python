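import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from portalwalk import (
    CollisionSite,
    CrossSection,
    CrossSectionState,
    DensityParams,
    FluidProperties,
    FourDTrajectory,
    GateStatus,
    WalkConfig,
    collision_distance,
    collision_probability_4d,
    rank_sites,
    required_steps,
    site_step_comparison,
    thrombus_gate,
)


def make_state(i: int, rho: float = 1.0) -> CrossSectionState:
    cs = CrossSection(
        segment_id="s", index=0, radius=5.0, axial_position=1.0, rho_i=rho
    )
    return CrossSectionState(
        cross_section=cs,
        initial_site=(0.0, 0.0),
        collision_site=(float(i), 0.0),
        distance=float(i),
        required_steps=i,
        reynolds=100.0,
        accel_m=0,
    )


class TestThrombusGate:
    @pytest.mark.parametrize(
        "factor, status",
        [(0.5, GateStatus.NO_THROMBUS), (1.0, GateStatus.FEASIBLE),
         (2.0, GateStatus.FEASIBLE)],
    )
    def test_gate_by_density_ratio(self, factor, status):
        assert thrombus_gate(factor * 3.0, 3.0) is status

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            thrombus_gate(-1.0, 1.0)

    @given(
        rho_m=st.floats(0.01, 100.0, allow_nan=False),
        frac=st.floats(0.0, 0.999, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_gate_dominance(self, rho_m, frac):
        """Below the minimum density no thrombus forms, whatever else holds."""
        assert thrombus_gate(frac * rho_m, rho_m) is GateStatus.NO_THROMBUS


class TestCollisionDistance:
    def test_reference_point(self):
        params = DensityParams(rho_m=2.0, p0=6.0)
        assert collision_distance(2.0, params) == pytest.approx(6.0)

    def test_quadruple_density_halves_distance(self):
        params = DensityParams(rho_m=2.0, p0=6.0)
        assert collision_distance(8.0, params) == pytest.approx(3.0)

    def test_monotone_decreasing(self):
        params = DensityParams(rho_m=1.0, p0=10.0)
        grid = np.linspace(1.0, 50.0, 40)
        dists = [collision_distance(r, params) for r in grid]
        assert all(a > b for a, b in zip(dists, dists[1:]))

    def test_below_gate_directs_to_gate(self):
        params = DensityParams(rho_m=2.0, p0=6.0)
        with pytest.raises(ValueError, match="thrombus_gate"):
            collision_distance(1.0, params)

    def test_custom_scaling_map(self):
        params = DensityParams(rho_m=1.0, p0=10.0)
        assert collision_distance(
            4.0, params, scaling=lambda ratio: 1.0 / ratio
        ) == pytest.approx(2.5)

    def test_sqrt_scaling_matches_nearest_neighbour_simulation(self):
        """Independent oracle: the mean nearest-neighbour distance of a
        uniform planar point set at density 4*rho is half that at rho."""
        rng = np.random.default_rng(12345)
        side = 20.0

        def mean_nn(density: float) -> float:
            n = int(density * side * side)
            pts = rng.uniform(0, side, size=(n, 2))
            d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            return float(np.sqrt(d2.min(axis=1)).mean())

        ratio = mean_nn(4.0) / mean_nn(1.0)
        assert ratio == pytest.approx(0.5, rel=0.08)


class TestRequiredSteps:
    @pytest.mark.parametrize(
        "distance, step, m, expected",
        [(10.0, 1.0, 0, 10), (10.0, 1.0, 3, 7), (0.4, 1.0, 5, 1),
         (10.5, 1.0, 0, 11), (9.0, 3.0, 1, 2)],
    )
    def test_ceil_minus_acceleration_floored_at_one(
        self, distance, step, m, expected
    ):
        assert required_steps(distance, step, m) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            required_steps(1.0, 0.0, 0)
        with pytest.raises(ValueError):
            required_steps(-1.0, 1.0, 0)


class TestSiteStepComparison:
    @pytest.mark.parametrize(
        "s, i, site",
        [
            (3, 5, CollisionSite.MAIN_PORTAL_VEIN),
            (5, 3, CollisionSite.OTHER_SITE),
            (4, 4, CollisionSite.INDETERMINATE),
        ],
    )
    def test_fewer_steps_wins(self, s, i, site):
        assert site_step_comparison(s, i) is site

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            site_step_comparison(0, 1)


class TestCollisionProbability4D:
    def test_single_state(self):
        traj = FourDTrajectory(states=(make_state(1),), L=0)
        assert collision_probability_4d(traj, 1.0) == pytest.approx(
            math.log(1 / 360)
        )

    def test_matches_exact_rational_product(self):
        """Sum of logs equals the log of the exact product (1/360)^5 * (1/2)^2."""
        traj = FourDTrajectory(states=(make_state(2), make_state(3)), L=2)
        log_p = collision_probability_4d(traj, 1.0)
        exact = Fraction(1, 360) ** 5 * Fraction(1, 2) ** 2
        assert log_p == pytest.approx(
            math.log(exact.numerator) - math.log(exact.denominator), rel=1e-12
        )

    def test_zero_step_state_rejected(self):
        with pytest.raises(ValueError):
            make_state(0)

    def test_empty_states_rejected(self):
        with pytest.raises(ValueError):
            FourDTrajectory(states=(), L=0)

    @given(
        steps_a=st.lists(st.integers(1, 20), min_size=1, max_size=5),
        steps_b=st.lists(st.integers(1, 20), min_size=1, max_size=5),
        la=st.integers(0, 4),
        lb=st.integers(0, 4),
        k=st.sampled_from([1 / 90, 1 / 36, 1.0]),
    )
    @settings(max_examples=50, deadline=None)
    def test_concatenation_is_additive(self, steps_a, steps_b, la, lb, k):
        """Product rule: the 4-D probability of concatenated trajectories is
        the product (sum in log space) of the parts."""
        ta = FourDTrajectory(tuple(make_state(i) for i in steps_a), L=la)
        tb = FourDTrajectory(tuple(make_state(i) for i in steps_b), L=lb)
        tab = FourDTrajectory(ta.states + tb.states, L=la + lb)
        assert collision_probability_4d(tab, k) == pytest.approx(
            collision_probability_4d(ta, k) + collision_probability_4d(tb, k),
            rel=1e-12,
        )


@pytest.fixture
def ranking_inputs(three_segment_tree, blood):
    walk_config = WalkConfig(k=1.0)
    density_params = DensityParams(rho_m=1.0, p0=6.0)
    accel = {"m_max": 5, "re_onset": 40.0, "re_saturation": 4000.0}
    return three_segment_tree, blood, walk_config, density_params, accel


class TestRankSites:
    def test_uniform_density_predicts_main_portal_vein(self, ranking_inputs):
        tree, blood, wc, dp, accel = ranking_inputs
        rho = {s.id: 1.0 for s in tree.segments}
        table = rank_sites(tree, rho, blood, wc, dp, accel)
        top = table.loc[table["rank"] == 1].iloc[0]
        assert top["segment_id"] == "mpv"
        assert bool(top["predicted"])

    def test_distal_density_moves_prediction(self, ranking_inputs):
        tree, blood, wc, dp, accel = ranking_inputs
        rho = {"mpv": 0.2, "left": 2.0, "right": 0.2}
        table = rank_sites(tree, rho, blood, wc, dp, accel)
        gated = table.set_index("segment_id")
        assert gated.loc["mpv", "gate"] == "no_thrombus"
        assert gated.loc["mpv", "rank"] is None or np.isnan(gated.loc["mpv", "rank"])
        top = table.loc[table["rank"] == 1].iloc[0]
        assert top["segment_id"] == "left"

    def test_identical_segments_tie_break_by_id(self, blood):
        from portalwalk import build_tree

        tree = build_tree(
            [
                {"id": "mpv", "diameter": 13.0, "length": 60.0,
                 "mean_velocity": 0.26},
                {"id": "a", "diameter": 9.0, "length": 40.0, "parent": "mpv",
                 "mean_velocity": 0.18},
                {"id": "b", "diameter": 9.0, "length": 40.0, "parent": "mpv",
                 "mean_velocity": 0.18},
            ]
        )
        table = rank_sites(
            tree,
            {s.id: 1.0 for s in tree.segments},
            blood,
            WalkConfig(k=1.0),
            DensityParams(rho_m=1.0, p0=6.0),
        )
        t = table.set_index("segment_id")
        assert t.loc["a", "log10_p_r4"] == t.loc["b", "log10_p_r4"]
        assert t.loc["a", "rank"] < t.loc["b", "rank"]

    def test_all_gated_gives_empty_ranking(self, ranking_inputs):
        tree, blood, wc, dp, accel = ranking_inputs
        rho = {s.id: 0.1 for s in tree.segments}
        table = rank_sites(tree, rho, blood, wc, dp, accel)
        assert (table["gate"] == "no_thrombus").all()
        assert not table["predicted"].any()
        assert table["rank"].isna().all()

    def test_missing_density_rejected(self, ranking_inputs):
        tree, blood, wc, dp, accel = ranking_inputs
        with pytest.raises(ValueError, match="missing"):
            rank_sites(tree, {"mpv": 1.0}, blood, wc, dp, accel)

    def test_raising_density_never_lowers_rank(self, ranking_inputs):
        """Composition consistency: more particles locally means fewer
        required steps and a no-worse rank."""
        tree, blood, wc, dp, accel = ranking_inputs
        base = {s.id: 1.0 for s in tree.segments}
        t0 = rank_sites(tree, base, blood, wc, dp, accel).set_index("segment_id")
        for boost in (4.0, 16.0, 64.0):
            rho = dict(base, left=boost)
            t1 = rank_sites(tree, rho, blood, wc, dp, accel).set_index("segment_id")
            assert t1.loc["left", "rank"] <= t0.loc["left", "rank"]
            t0 = t1

    def test_ordering_matches_effective_step_count(self, ranking_inputs):
        """Monotone-transform stability: ordering by log p(R4) equals
        ordering by the effective step count."""
        tree, blood, wc, dp, accel = ranking_inputs
        rng = np.random.default_rng(5)
        for _ in range(5):
            rho = {s.id: float(rng.uniform(1.0, 20.0)) for s in tree.segments}
            table = rank_sites(tree, rho, blood, wc, dp, accel)
            feasible = table.dropna(subset=["rank"])
            log_step = math.log(1 / 360)
            eff = feasible["i_total"] + feasible["L"] * math.log(0.5) / log_step
            # smaller effective step count <=> larger log p <=> better rank
            assert list(feasible.sort_values("rank")["segment_id"]) == list(
                feasible.assign(eff=eff)
                .sort_values(["eff", "segment_id"])["segment_id"]
            )

    def test_minimal_probability_ordering_exportable(self, ranking_inputs):
        tree, blood, wc, dp, accel = ranking_inputs
        rho = {s.id: 1.0 for s in tree.segments}
        table = rank_sites(tree, rho, blood, wc, dp, accel, ascending=True)
        top = table.loc[table["rank"] == 1].iloc[0]
        assert top["segment_id"] != "mpv"
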