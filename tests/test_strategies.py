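"""The four built strategy models: structure, transitions, accruals."""

import numpy as np
import pytest

from lvad_cea.economics import evaluate_model
from lvad_cea.engine import run_cohort
from lvad_cea.parameters import load_parameters, to_dict
from lvad_cea.strategies import (
    build_btt_control,
    build_btt_intervention,
    build_dt_control,
    build_dt_intervention,
    build_pair,
    pump_complication_mixture,
)


def reload_with(params, edit):
    """Re-load the parameter set after applying ``edit`` to its dict form."""
    tree = to_dict(params)
    edit(tree)
    return load_parameters(tree, merge_defaults=False)


def zero_complications(tree):
    for comp in tree["pump"]["complications"]:
        n = len(comp["rate"]["values"])
        comp["rate"]["values"] = [0.0] * n
        comp["rate"]["lows"] = [0.0] * n
        comp["rate"]["highs"] = [0.0] * n


class TestDtControl:
    def test_undiscounted_lifetime_qaly_matches_geometric_oracle(self, params, ss_costs):
        model = build_dt_control(params, ss_costs)
        trace = run_cohort(model, discount_rate=0.0)
        assert trace.total_qaly_undisc == pytest.approx(
            (0.53 / 12) / 0.106, rel=1e-5)

    def test_discounted_lifetime_qaly(self, params, ss_costs):
        model = build_dt_control(params, ss_costs)
        trace = run_cohort(model, discount_rate=0.05)
        d = 1.05 ** (-1 / 12)
        closed = (0.53 / 12) / (1 - (1 - 0.106) * d)
        assert trace.total_qaly_disc == pytest.approx(closed, rel=1e-5)
        assert 0.39 < trace.total_qaly_disc < 0.41

    def test_certain_death_gives_single_cycle_accrual(self, params, ss_costs):
        p = reload_with(params, lambda t: t["model1"].update(
            {"p_death_medtx": {"base": 1.0}}))
        trace = run_cohort(build_dt_control(p, ss_costs), discount_rate=0.0)
        assert trace.total_qaly_undisc == pytest.approx(0.53 / 12)

    def test_blended_monthly_cost(self, params, ss_costs):
        model = build_dt_control(params, ss_costs)
        expected = (0.25 * ss_costs.monthly["medtx_hospitalized"]
                    + 0.75 * ss_costs.monthly["medtx_outpatient"])
        assert model.running_cost("MedTx", 0) == pytest.approx(expected)


class TestDtIntervention:
    def test_month_one_complication_entry_probability(self, params, ss_costs):
        """Entry into the pooled complication state at month 1 is the sum of
        the published month-1 incidence rates, 0.1198."""
        model = build_dt_intervention(params, ss_costs)
        mat = model.transition(0)
        i_stable = model.states.index("PumpStable")
        i_comp = model.states.index("PumpComplication")
        assert mat[i_stable, i_comp] == pytest.approx(0.1198)
        assert mat[i_stable, model.death_index] == pytest.approx(0.06)

    def test_arrhythmia_contributes_pump_utility_minus_decrement(self, params, ss_costs):
        """With only the arrhythmia active, the complication-state utility is
        the ongoing pump utility plus the disutility: 0.72 - 0.02."""
        def only_arrhythmia(tree):
            for comp in tree["pump"]["complications"]:
                if comp["name"] != "ventricular_arrhythmia":
                    n = len(comp["rate"]["values"])
                    comp["rate"]["values"] = [0.0] * n
                    comp["rate"]["lows"] = [0.0] * n
                    comp["rate"]["highs"] = [0.0] * n
        p = reload_with(params, only_arrhythmia)
        total, u_mix, _ = pump_complication_mixture(p, ss_costs, month=2)
        assert total == pytest.approx(0.014)
        assert u_mix == pytest.approx(0.70)

    def test_zero_complications_reduce_to_pump_survival_closed_form(
            self, params, ss_costs):
        """Without complications the intervention is a two-state survival
        model under the piecewise mortality schedule; the engine must match
        an explicit product-form accumulation."""
        p = reload_with(params, zero_complications)
        model = build_dt_intervention(p, ss_costs)
        trace = run_cohort(model, horizon=600, discount_rate=0.05)
        d = 1.05 ** (-1 / 12)
        expected, surv = 0.0, 1.0
        for t in range(600):
            u = 0.51 if t == 0 else 0.72
            expected += surv * u / 12 * d**t
            surv *= 1.0 - p.pump_mortality.at(t + 1)
        assert trace.total_qaly_disc == pytest.approx(expected, rel=1e-10)

    def test_device_and_implantation_charged_at_entry(self, params, ss_costs):
        model = build_dt_intervention(params, ss_costs)
        trace = run_cohort(model, horizon=1, discount_rate=0.0)
        upfront = ss_costs.device_price + ss_costs.one_time["pump_implantation"]
        assert trace.total_cost_undisc == pytest.approx(
            upfront + ss_costs.monthly["pump_stable"])

    def test_qaly_strictly_decreases_with_mortality(self, params, ss_costs):
        """Monotonicity: scaling the whole mortality schedule up can only
        lower lifetime QALYs."""
        def scaled(factor):
            def edit(tree):
                zero_complications(tree)
                m = tree["pump"]["mortality"]
                m["values"] = [v * factor for v in m["values"]]
                m["lows"] = [0.0] * len(m["values"])
                m["highs"] = [1.0] * len(m["values"])
            p = reload_with(params, edit)
            model = build_dt_intervention(p, ss_costs)
            return run_cohort(model, discount_rate=0.05).total_qaly_disc

        values = [scaled(f) for f in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestBttControl:
    def test_survival_into_transplant_surgery(self, params, ss_costs):
        """Mass reaching surgery equals (1-p)^3.05 under the fractional-cycle
        rule: three full waiting cycles plus a 0.05-month exit cycle."""
        model = build_btt_control(params, ss_costs)
        trace = run_cohort(model, discount_rate=0.05)
        i_surg = model.states.index("TransplantSurgery")
        arriving = trace.membership[4, i_surg]
        assert arriving == pytest.approx(0.894**3.05, rel=1e-12)
        # perioperative deaths before the post-transplant state
        i_post = model.states.index("PostTx")
        assert trace.membership[5, i_post] == pytest.approx(
            0.894**3.05 * (1 - 0.074), rel=1e-12)

    def test_zero_wait_enters_surgery_immediately(self, params, ss_costs):
        p = reload_with(params, lambda t: t["model2"].update(
            {"wait_ht": {"base": 0.0, "low": 0.0, "high": 9.0}}))
        model = build_btt_control(p, ss_costs)
        assert model.initial[model.states.index("TransplantSurgery")] == 1.0

    def test_discounted_lifetime_qaly_magnitude(self, params, ss_costs):
        trace = run_cohort(build_btt_control(params, ss_costs), discount_rate=0.05)
        assert 5.5 < trace.total_qaly_disc < 7.0


class TestBttIntervention:
    def test_transplant_timing_with_fractional_wait(self, params, ss_costs):
        """wait of 6.07 months: six full cycles, a 0.07-month fractional
        cycle, surgery occupying the next cycle."""
        model = build_btt_intervention(params, ss_costs)
        trace = run_cohort(model, discount_rate=0.05)
        i_frac = model.states.index("PumpWaitFrac")
        i_surg = model.states.index("TransplantSurgery")
        assert trace.membership[6, i_frac] > 0
        assert trace.membership[6, i_surg] == 0
        assert trace.membership[7, i_surg] > 0
        assert model.occupancy[i_frac] == pytest.approx(0.07)

    def test_incremental_qaly_increases_with_control_waiting_time(
            self, params, ss_costs):
        """Longer waits on the direct-transplant list favor the pump arm."""
        deltas = []
        for wait in range(2, 10):
            p = reload_with(params, lambda t, w=wait: t["model2"].update(
                {"wait_ht": {"base": float(w), "low": 2.0, "high": 9.0}}))
            res = evaluate_model("BTT", p, ss_costs)
            deltas.append(res.discounted.delta_effect)
        assert all(b > a for a, b in zip(deltas, deltas[1:]))


class TestStructuralInvariants:
    @pytest.mark.parametrize("model_id", ["DT", "BTT"])
    def test_built_models_are_row_stochastic_with_absorbing_death(
            self, params, ss_costs, model_id):
        for model in build_pair(model_id, params, ss_costs):
            for t in list(range(0, 70)) + [200, 1199]:
                mat = model.transition(t)  # raises on any violation
                assert np.abs(mat.sum(axis=1) - 1.0).max() < 1e-12
                death = np.zeros(len(model.states))
                death[model.death_index] = 1.0
                assert np.allclose(mat[model.death_index], death)

    @pytest.mark.parametrize("model_id", ["DT", "BTT"])
    def test_cohort_conservation_and_absorption(self, params, ss_costs, model_id):
        for model in build_pair(model_id, params, ss_costs):
            trace = run_cohort(model, discount_rate=0.05)
            assert np.abs(trace.membership.sum(axis=1) - 1.0).max() < 1e-10
            assert (np.diff(trace.membership[:, model.death_index]) >= -1e-12).all()
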