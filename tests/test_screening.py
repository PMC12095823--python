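"""Screening metrics, interaction calls, viability, cross-feeding and scans."""

import math

import pytest
from hypothesis import given, strategies as st

from commscreen.dfba import CommunityState, CommunityTrajectory, SimulationConfig
from commscreen.environments import Medium
from commscreen.model_io import OBLIGATE_ANAEROBE
from commscreen.screening import (
    check_viability,
    classify_interaction,
    classify_pair,
    cross_feeding_roles,
    lhs_sensitivity,
    productivity,
    productivity_ratio,
    rank_systems,
    scan_carbon_sources,
    scan_inoculum,
    screen_pairs,
    yield_per_substrate,
)
from commscreen.toys import P1_EXCHANGE, P2_EXCHANGE, toy_a, toy_b, toy_c


def _fake_trajectory(x0, x_end, products=None, s0=None, s_end=None,
                     horizon=12.0):
    """Hand-assembled trajectory for exact metric arithmetic."""
    species = list(x0)
    products = products or {}
    config = SimulationConfig(horizon=horizon)
    p = {key: val for key, val in products.items()}
    initial = CommunityState(0.0, dict(x0), dict(s0 or {}),
                             {k: 0.0 for k in p}, {sp: 0.0 for sp in species},
                             {sp: True for sp in species})
    final = CommunityState(horizon, dict(x_end), dict(s_end or {}), p,
                           {sp: 0.0 for sp in species},
                           {sp: True for sp in species})
    total = sum(x_end.values())
    return CommunityTrajectory(
        species=species,
        states=[initial, final],
        terminal_state=final,
        abundances={sp: x_end[sp] / total for sp in species},
        inoculum=dict(x0),
        config=config,
        products=tuple({prod for prod, _ in p}),
        medium_name="fake",
        exchange_records=[],
    )


# ---------------------------------------------------------------------------
# Productivity and its ratio
# ---------------------------------------------------------------------------

class TestProductivity:
    def test_terminal_product_over_horizon(self):
        traj = _fake_trajectory({"a": 0.01}, {"a": 0.5},
                                products={("EX_p_e", "a"): 0.768})
        assert productivity(traj, "EX_p_e") == pytest.approx(0.064)

    def test_zero_production(self):
        traj = _fake_trajectory({"a": 0.01}, {"a": 0.5},
                                products={("EX_p_e", "a"): 0.0})
        assert productivity(traj, "EX_p_e") == 0.0

    def test_untracked_product_is_an_error(self):
        traj = _fake_trajectory({"a": 0.01}, {"a": 0.5})
        with pytest.raises(KeyError):
            productivity(traj, "EX_p_e")

    def test_longer_horizon_dilutes_rate(self):
        t12 = _fake_trajectory({"a": 0.01}, {"a": 0.5},
                               products={("EX_p_e", "a"): 0.768}, horizon=12.0)
        t24 = _fake_trajectory({"a": 0.01}, {"a": 0.5},
                               products={("EX_p_e", "a"): 0.768}, horizon=24.0)
        assert productivity(t24, "EX_p_e") == \
            pytest.approx(productivity(t12, "EX_p_e") / 2)


class TestProductivityRatio:
    def test_published_style_worked_example(self):
        # community 0.064 vs monocultures (0, 0.0519) mmol/L/h
        result = productivity_ratio(0.0640, 0.0, 0.0519)
        assert result.delta == pytest.approx(0.0121, abs=5e-5)
        assert result.ratio * 100 == pytest.approx(23.31, abs=0.01)
        assert result.category == "ratio"

    def test_equal_to_best_mono_is_zero(self):
        assert productivity_ratio(0.2, 0.2, 0.1).ratio == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert productivity_ratio(0.5, 0.2, 0.1).ratio == pytest.approx(1.5)

    def test_high_sentinel_when_monocultures_silent(self):
        result = productivity_ratio(0.05, 0.0, 0.0)
        assert result.category == "high"
        assert math.isinf(result.ratio)

    def test_no_production_anywhere(self):
        result = productivity_ratio(0.0, 0.0, 0.0)
        assert result.category == "no_production"
        assert math.isnan(result.ratio)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            productivity_ratio(-0.1, 0.0, 0.0)

    @given(c=st.floats(min_value=1e-3, max_value=1e3),
           comm=st.floats(min_value=0.01, max_value=10),
           mono_a=st.floats(min_value=0.01, max_value=10),
           mono_b=st.floats(min_value=0.01, max_value=10))
    def test_scale_invariance(self, c, comm, mono_a, mono_b):
        base = productivity_ratio(comm, mono_a, mono_b)
        scaled = productivity_ratio(c * comm, c * mono_a, c * mono_b)
        assert scaled.ratio == pytest.approx(base.ratio, rel=1e-9)


# ---------------------------------------------------------------------------
# Interaction classification
# ---------------------------------------------------------------------------

class TestClassifyInteraction:
    @pytest.mark.parametrize("comm_a,comm_b,expected_signs,expected_label", [
        (0.6, 0.3, ("+", "-"), "parasitism"),    # 0.6>0.55, 0.3<0.45
        (0.5, 0.5, ("0", "0"), "neutralism"),    # both inside the band
        (0.44, 0.44, ("-", "-"), "competition"),  # both below 0.45
        (0.6, 0.6, ("+", "+"), "mutualism"),
        (0.6, 0.5, ("+", "0"), "commensalism"),
        (0.44, 0.5, ("-", "0"), "amensalism"),
    ])
    def test_six_way_map(self, comm_a, comm_b, expected_signs, expected_label):
        call = classify_interaction(comm_a, comm_b, 1.0, 1.0, threshold=0.1)
        assert call.signs == expected_signs
        assert call.label == expected_label

    def test_swap_invariance_mirrors_signs(self):
        forward = classify_interaction(0.6, 0.3, 1.0, 1.0)
        backward = classify_interaction(0.3, 0.6, 1.0, 1.0)
        assert forward.label == backward.label == "parasitism"
        assert forward.signs == tuple(reversed(backward.signs))

    def test_zero_monoculture_growth_is_undefined(self):
        call = classify_interaction(0.5, 0.5, 0.0, 1.0)
        assert call.label == "undefined"
        assert call.signs[0] == "?"

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify_interaction(1, 1, 1, 1, threshold=0.0)

    @given(comm_a=st.floats(min_value=0, max_value=10),
           comm_b=st.floats(min_value=0, max_value=10),
           mono_a=st.floats(min_value=1e-6, max_value=10),
           mono_b=st.floats(min_value=1e-6, max_value=10))
    def test_total_function_over_positive_monocultures(self, comm_a, comm_b,
                                                       mono_a, mono_b):
        call = classify_interaction(comm_a, comm_b, mono_a, mono_b)
        assert call.label in {"competition", "amensalism", "parasitism",
                              "neutralism", "commensalism", "mutualism"}


class TestEngineeredInteractions:
    def test_cross_feeding_pair_is_cooperative(self, trajectories):
        call = classify_pair(trajectories["ab"], trajectories["mono_a"],
                             trajectories["mono_b"])
        assert call.label in ("commensalism", "mutualism")

    def test_competition_pair_is_antagonistic(self, trajectories):
        call = classify_pair(trajectories["ac"], trajectories["mono_a"],
                             trajectories["mono_c"])
        assert call.label in ("competition", "amensalism")
        # toy_a is the harmed side: it loses glucose and its salvageable acetate
        assert call.signs[0] == "-"


# ---------------------------------------------------------------------------
# Viability
# ---------------------------------------------------------------------------

class TestViability:
    def test_low_abundance_member_fails(self):
        traj = _fake_trajectory({"a": 0.01, "b": 0.01}, {"a": 0.30, "b": 0.02})
        result = check_viability(traj)
        assert not result.viable
        assert any("abundance[b]" in f for f in result.failed)

    def test_balanced_growing_community_is_viable(self):
        traj = _fake_trajectory({"a": 0.01, "b": 0.01}, {"a": 0.30, "b": 0.10})
        assert check_viability(traj).viable

    def test_no_growth_fails_growth_criterion(self):
        traj = _fake_trajectory({"a": 0.01, "b": 0.01}, {"a": 0.01, "b": 0.01})
        result = check_viability(traj)
        assert not result.viable
        assert any("growth" in f for f in result.failed)

    def test_partner_viable_only_in_coculture(self, trajectories):
        assert not check_viability(trajectories["mono_b"]).viable
        assert check_viability(trajectories["ab"]).viable


# ---------------------------------------------------------------------------
# Cross-feeding
# ---------------------------------------------------------------------------

class TestCrossFeeding:
    def test_acetate_producer_and_consumer_roles(self, trajectories):
        table = cross_feeding_roles(trajectories["ab"])
        acetate = table[table.metabolite == "ac_e"].set_index("species")
        assert acetate.loc["toy_a", "role"] == "Producer"
        assert acetate.loc["toy_b", "role"] == "Consumer"
        assert bool(acetate.cross_feeding.all())

    def test_monoculture_has_no_cross_feeding(self, trajectories):
        table = cross_feeding_roles(trajectories["mono_a"])
        assert not table.cross_feeding.any()

    def test_all_zero_fluxes_empty_table(self, trajectories):
        traj = trajectories["mono_b"]  # nothing consumable: no flux at all
        table = cross_feeding_roles(traj)
        assert table.empty or (table.role == "none").all()


# ---------------------------------------------------------------------------
# Yield
# ---------------------------------------------------------------------------

class TestYield:
    MASSES = {"p_e": 90.0, "glc__D_e": 180.0}

    def test_hand_arithmetic(self):
        traj = _fake_trajectory({"a": 0.01}, {"a": 0.5},
                                products={("EX_p_e", "a"): 10.0},
                                s0={"glc__D_e": 30.0}, s_end={"glc__D_e": 10.0})
        value = yield_per_substrate(traj, "EX_p_e", "glc__D_e", self.MASSES)
        assert value == pytest.approx(0.25)  # (10*90)/(20*180)

    def test_zero_production(self):
        traj = _fake_trajectory({"a": 0.01}, {"a": 0.5},
                                products={("EX_p_e", "a"): 0.0},
                                s0={"glc__D_e": 30.0}, s_end={"glc__D_e": 10.0})
        assert yield_per_substrate(traj, "EX_p_e", "glc__D_e", self.MASSES) == 0.0

    def test_undefined_without_consumption(self):
        traj = _fake_trajectory({"a": 0.01}, {"a": 0.5},
                                products={("EX_p_e", "a"): 1.0},
                                s0={"glc__D_e": 10.0}, s_end={"glc__D_e": 10.0})
        assert math.isnan(
            yield_per_substrate(traj, "EX_p_e", "glc__D_e", self.MASSES)
        )


# ---------------------------------------------------------------------------
# Pairwise screen
# ---------------------------------------------------------------------------

class TestScreenPairs:
    def test_record_counting(self, minimal_medium, default_config):
        records = screen_pairs([toy_a(), toy_b()], [minimal_medium],
                               [P1_EXCHANGE, P2_EXCHANGE], default_config)
        assert len(records) == 6  # 2 monocultures x 2 products + 1 pair x 2
        assert sum(len(r.system) == 2 for r in records) == 2

    def test_single_model_yields_monoculture_records_only(self, minimal_medium,
                                                          default_config):
        records = screen_pairs([toy_a()], [minimal_medium], [P1_EXCHANGE],
                               default_config)
        assert len(records) == 1
        assert all(len(r.system) == 1 for r in records)

    def test_monoculture_baseline_identical_to_standalone_run(
            self, minimal_medium, default_config, trajectories):
        records = screen_pairs([toy_a()], [minimal_medium], [P1_EXCHANGE],
                               default_config)
        standalone = trajectories["mono_a"]
        assert records[0].terminal_biomass == standalone.terminal_state.X
        assert records[0].productivity == \
            pytest.approx(productivity(standalone, P1_EXCHANGE), rel=1e-12)

    def test_obligate_regime_exclusion(self, default_config):
        anaerobe = toy_c()
        anaerobe.oxygen_requirement = OBLIGATE_ANAEROBE
        aerobic = Medium("aer", {"glc__D_e": 10.0, "o2_e": 10.0}, "aerobic")
        records = screen_pairs([toy_a(), anaerobe], [aerobic], [P1_EXCHANGE],
                               default_config)
        systems = {r.system for r in records}
        assert ("toy_a",) in systems
        assert all("toy_c" not in r.system for r in records)

    def test_rank_systems_orders_by_productivity(self, minimal_medium,
                                                 default_config):
        records = screen_pairs([toy_a(), toy_b()], [minimal_medium],
                               [P1_EXCHANGE], default_config)
        ranked = rank_systems(records, P1_EXCHANGE, minimal_medium.name, top=5)
        values = [r.productivity for r in ranked]
        assert values == sorted(values, reverse=True)


def test_carbon_scan_runs_per_source(default_config):
    medium = Medium("m", {"glc__D_e": 10.0}, "anaerobic")
    records = scan_carbon_sources([toy_a()], [medium], ["glc__D_e", "xyl__D_e"],
                                  [P1_EXCHANGE], default_config)
    by_carbon = {r.carbon_source for r in records}
    assert by_carbon == {"glc__D_e", "xyl__D_e"}
    # toy_a cannot import xylose: no growth-driven production there
    xyl = [r for r in records if r.carbon_source == "xyl__D_e"][0]
    glc = [r for r in records if r.carbon_source == "glc__D_e"][0]
    assert glc.productivity > xyl.productivity


# ---------------------------------------------------------------------------
# Inoculum scan
# ---------------------------------------------------------------------------

class TestScanInoculum:
    RATIOS = [(0.9, 0.1), (0.5, 0.5), (0.1, 0.9)]

    def test_table_is_self_consistent(self, minimal_medium, default_config):
        table = scan_inoculum([toy_a(), toy_c()], self.RATIOS, 0.02,
                              minimal_medium, default_config,
                              product_id=P1_EXCHANGE)
        assert len(table) == 3
        for row in table.itertuples():
            assert row.total_biomass_g_per_L == pytest.approx(
                row.biomass_a_g_per_L + row.biomass_b_g_per_L, rel=1e-9)
            assert row.abundance_a == pytest.approx(
                row.biomass_a_g_per_L / row.total_biomass_g_per_L, rel=1e-9)

    def test_competitor_abundance_monotone_in_its_inoculum(self,
                                                           minimal_medium,
                                                           default_config):
        ratios = [(0.9, 0.1), (0.7, 0.3), (0.5, 0.5), (0.3, 0.7), (0.1, 0.9)]
        table = scan_inoculum([toy_a(), toy_c()], ratios, 0.02,
                              minimal_medium, default_config)
        abundance_c = list(table.abundance_b)
        assert all(b >= a - 1e-9 for a, b in zip(abundance_c, abundance_c[1:]))

    def test_bad_ratio_rejected(self, minimal_medium, default_config):
        with pytest.raises(ValueError):
            scan_inoculum([toy_a(), toy_c()], [(0.6, 0.5)], 0.02,
                          minimal_medium, default_config)

    def test_needs_exactly_two_models(self, minimal_medium, default_config):
        with pytest.raises(ValueError):
            scan_inoculum([toy_a()], self.RATIOS, 0.02, minimal_medium,
                          default_config)


# ---------------------------------------------------------------------------
# LHS sensitivity
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def dense_culture_config():
    """A dense inoculum makes nutrient availability, not transport kinetics,
    the binding uptake limit for every draw in the sampled ranges."""
    return SimulationConfig(initial_biomass=200.0)


class TestLHSSensitivity:
    def test_same_seed_reproduces_everything(self, minimal_medium,
                                             dense_culture_config):
        first = lhs_sensitivity([toy_a()], minimal_medium,
                                dense_culture_config, n=5, seed=11)
        second = lhs_sensitivity([toy_a()], minimal_medium,
                                 dense_culture_config, n=5, seed=11)
        assert first.same_draws(second)
        assert first.coefficients == second.coefficients
        assert first.r_squared == second.r_squared

    def test_draws_are_stratified(self, minimal_medium, dense_culture_config):
        n = 10
        result = lhs_sensitivity([toy_a()], minimal_medium,
                                 dense_culture_config, n=n, seed=3)
        for column, (lo, hi) in (("v_max", (1.0, 50.0)), ("k_m", (0.01, 1.0))):
            strata = sorted(int((v - lo) / (hi - lo) * n)
                            for v in result.draws[column])
            assert strata == list(range(n))

    def test_availability_limited_culture_is_insensitive(self, minimal_medium,
                                                         dense_culture_config):
        result = lhs_sensitivity([toy_a()], minimal_medium,
                                 dense_culture_config, n=10, seed=7)
        assert abs(result.coefficients_std_inputs["v_max"]) < 0.01
        assert abs(result.coefficients_std_inputs["k_m"]) < 0.01
        assert result.r_squared == pytest.approx(0.0, abs=1e-9)

    def test_needs_enough_draws(self, minimal_medium, dense_culture_config):
        with pytest.raises(ValueError):
            lhs_sensitivity([toy_a()], minimal_medium, dense_culture_config,
                            n=2, seed=1)
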