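"""Tornado DSA, waiting-time scenario, PSA, CEAC and CE plane."""

import numpy as np
import pytest

from lvad_cea.distributions import draw_beta, draw_estimate, range_to_se
from lvad_cea.economics import evaluate_model
from lvad_cea.errors import ValidationError
from lvad_cea.parameters import Estimate, load_parameters, to_dict
from lvad_cea.sensitivity import (
    PSADraws,
    ce_plane,
    ceac,
    ceac_thresholds,
    one_way_dsa,
    psa,
    waiting_time_scenario,
)


@pytest.fixture(scope="module")
def dt_tornado(params, ss_costs):
    return one_way_dsa("DT", params, ss_costs)


class TestOneWayDsa:
    def test_rows_sorted_by_descending_swing(self, dt_tornado):
        swings = [r.swing for r in dt_tornado]
        assert swings == sorted(swings, reverse=True)

    def test_base_value_reproduces_base_icer_exactly(self, params, ss_costs):
        """Round-tripping the parameters through the DSA re-load machinery
        must reproduce the base ICER bit-for-bit."""
        base = evaluate_model("DT", params, ss_costs).discounted.icer.value
        reloaded = load_parameters(to_dict(params), merge_defaults=False)
        again = evaluate_model("DT", reloaded, ss_costs).discounted.icer.value
        assert again == base

    def test_degenerate_range_has_zero_swing(self):
        from lvad_cea.sensitivity import TornadoRow
        row = TornadoRow("degenerate", 0.106, 0.106, 123.0, 123.0)
        assert row.swing == 0.0

    def test_higher_discount_rate_raises_dt_icer(self, params, ss_costs, dt_tornado):
        base = evaluate_model("DT", params, ss_costs).discounted.icer.value
        row = next(r for r in dt_tornado if r.parameter == "discount_rate")
        assert row.icer_low < base < row.icer_high

    def test_cheaper_device_lowers_dt_icer(self, params, ss_costs, dt_tornado):
        base = evaluate_model("DT", params, ss_costs).discounted.icer.value
        row = next(r for r in dt_tornado if r.parameter == "cost:device_price")
        assert row.icer_low < base < row.icer_high

    def test_skips_parameters_without_ranges(self, dt_tornado):
        # transplant-complication *rates* carry no range and must not appear
        # (their episode costs still do, under the cost: prefix)
        rate_items = {r.parameter for r in dt_tornado
                      if not r.parameter.startswith("cost:")}
        assert not any("rejection" in n for n in rate_items)


class TestWaitingTimeScenario:
    def test_icer_strictly_decreasing_in_waiting_time(self, params, ss_costs):
        """Longer waits make the bridge strategy relatively more attractive,
        the direction reported for the published scenario endpoints."""
        df = waiting_time_scenario(
            list(range(2, 10)), params, ss_costs, equal_waits=True)
        icers = df["icer"].to_numpy()
        assert (np.diff(icers) < 0).all()

    def test_short_wait_far_above_long_wait(self, params, ss_costs):
        df = waiting_time_scenario([1.5, 9.0], params, ss_costs)
        short, long = df["icer"].to_numpy()
        assert short > 3 * long

    def test_nonpositive_wait_rejected(self, params, ss_costs):
        with pytest.raises(ValidationError):
            waiting_time_scenario([0.0], params, ss_costs)


class TestDistributions:
    def test_beta_moment_recovery(self):
        """Method-of-moments beta draws recover the configured mean and SD
        within three Monte-Carlo standard errors."""
        rng = np.random.default_rng(7)
        n = 10_000
        draws = np.array([draw_beta(0.53, 0.135, rng) for _ in range(n)])
        assert abs(draws.mean() - 0.53) < 3 * 0.135 / np.sqrt(n)
        assert abs(draws.std(ddof=1) - 0.135) < 3 * 0.135 / np.sqrt(2 * n)

    def test_range_read_as_95_interval(self):
        rng = np.random.default_rng(11)
        est = Estimate(base=0.106, low=0.079, high=0.132)
        se = range_to_se(0.079, 0.132)
        n = 4000
        draws = np.array([draw_estimate(est, rng).base for _ in range(n)])
        assert abs(draws.mean() - 0.106) < 3 * se / np.sqrt(n)

    def test_zero_width_returns_base_exactly(self):
        rng = np.random.default_rng(1)
        est = Estimate(base=0.3, se=0.0)
        assert draw_estimate(est, rng) is est

    def test_infeasible_se_clamped_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        with caplog.at_level("WARNING"):
            value = draw_beta(0.2, 0.9, rng)
        assert 0.0 < value < 1.0
        assert "clamped" in caplog.text


@pytest.fixture(scope="module")
def dt_draws(params, ss_costs):
    return psa("DT", params, {"SS": ss_costs}, n_iter=120, seed=5)


class TestPsa:
    def test_seeded_reproducibility_bit_exact(self, params, ss_costs, dt_draws):
        again = psa("DT", params, {"SS": ss_costs}, n_iter=120, seed=5)
        assert (again.delta_cost["SS"] == dt_draws.delta_cost["SS"]).all()
        assert (again.delta_effect["SS"] == dt_draws.delta_effect["SS"]).all()
        other = psa("DT", params, {"SS": ss_costs}, n_iter=10, seed=6)
        assert not np.array_equal(other.delta_cost["SS"],
                                  dt_draws.delta_cost["SS"][:10])

    def test_degenerate_distributions_reproduce_base_case(
            self, degenerate_params, ss_costs):
        from lvad_cea.synthetic import perturb_parameters
        assert perturb_parameters(degenerate_params, 3) == degenerate_params

    def test_draw_count_and_finiteness(self, dt_draws):
        assert dt_draws.n_iter == 120
        assert np.isfinite(dt_draws.delta_cost["SS"]).all()
        assert np.isfinite(dt_draws.delta_effect["SS"]).all()

    def test_draws_dominated_by_northeast_quadrant(self, dt_draws):
        """The pump adds both QALYs and cost in essentially every draw."""
        df = ce_plane(dt_draws)
        assert (df["quadrant"] == "NE").mean() >= 0.99


class TestCeac:
    def make_draws(self, pairs):
        dc = np.array([c for c, _ in pairs], dtype=float)
        de = np.array([e for _, e in pairs], dtype=float)
        return PSADraws("DT", 0, len(pairs), {"SS": dc}, {"SS": de}, 0.05)

    def test_hand_built_draws(self):
        draws = self.make_draws([(1, 1), (3, 1), (5, 1), (7, 1)])
        df = ceac(draws, [4.0])
        assert df["probability"].iloc[0] == 0.5

    def test_dominant_draws_always_accepted(self):
        draws = self.make_draws([(-1, 1)] * 5)
        df = ceac(draws, [0.0, 10.0, 1e9])
        assert (df["probability"] == 1.0).all()

    def test_costlier_equal_effect_never_accepted(self):
        draws = self.make_draws([(1, 0)] * 5)
        df = ceac(draws, [0.0, 1e12])
        assert (df["probability"] == 0.0).all()

    def test_limits_and_monotonicity(self, dt_draws):
        """CEAC(0) is the fraction of cost-saving draws; as wtp grows it
        approaches the fraction of QALY-gaining draws, monotonically when
        every draw gains QALYs."""
        dc = dt_draws.delta_cost["SS"]
        de = dt_draws.delta_effect["SS"]
        grid = ceac_thresholds(700_473.0)
        df = ceac(dt_draws, grid)
        probs = df["probability"].to_numpy()
        assert probs[0] == (dc < 0).mean()
        huge = ceac(dt_draws, [1e15])["probability"].iloc[0]
        assert huge == (de > 0).mean()
        if (de >= 0).all():
            assert (np.diff(probs) >= 0).all()

    def test_threshold_grid_contains_integer_gdp_points(self):
        grid = ceac_thresholds(700_473.0)
        for k in range(1, 6):
            assert np.isclose(grid, k * 700_473.0).any()


class TestCePlane:
    @pytest.mark.parametrize(
        "delta, quadrant",
        [((1.0, 1.0), "NE"), ((-1.0, 1.0), "NW"), ((1.0, -1.0), "SE"),
         ((-1.0, -1.0), "SW")],
    )
    def test_quadrant_labels(self, delta, quadrant):
        de, dc = delta
        draws = PSADraws("DT", 0, 1, {"SS": np.array([dc])},
                         {"SS": np.array([de])}, 0.05)
        assert ce_plane(draws)["quadrant"].iloc[0] == quadrant

    def test_export_layout(self, tmp_path, dt_draws):
        path = tmp_path / "plane.csv"
        from lvad_cea.sensitivity import ce_plane_export
        df = ce_plane_export(dt_draws, path)
        assert path.exists()
        assert {"delta_qaly", "delta_cost", "quadrant"} <= set(df.columns)
        assert len(df) == dt_draws.n_iter
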