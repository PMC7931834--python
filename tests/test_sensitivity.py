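"""Parameter paths, one-/two-way sweeps, and break-even solving."""

import numpy as np
import pytest

from vlcost import sensitivity as sens
from vlcost.parameters import Specimen


class TestParameterPaths:
    @pytest.mark.parametrize(
        "path, expected",
        [
            ("unit_costs.psc.consumables", 5.00),
            ("assays.dbs.capctm.specificity", 0.939),
            ("multipliers.low_volume_plasma", 0.40),
            ("visit_transport.visit_cost", 3.65),
            ("visit_transport.transport_cost_by_scenario.dried_full", 2_390_317.0),
        ],
    )
    def test_get(self, zambia_config, path, expected):
        assert sens.get_param(zambia_config, path) == expected

    def test_set_returns_copy(self, zambia_config):
        new = sens.set_param(zambia_config, "unit_costs.psc.consumables", 2.72)
        assert new.unit_cost(Specimen.PSC).consumables == 2.72
        assert zambia_config.unit_cost(Specimen.PSC).consumables == 5.00

    def test_setting_point_estimate_widens_bounds(self, zambia_config):
        new = sens.set_param(zambia_config, "assays.plasma.capctm.sensitivity", 0.5)
        a = new.assay(Specimen.PLASMA, sens.Platform.CAPCTM)
        assert a.sens_low <= 0.5 <= a.sens_high

    @pytest.mark.parametrize("path", ["nonsense.x", "unit_costs.psc.kit", "assays.psc.abbott.sensitivity"])
    def test_unresolvable_paths_raise(self, zambia_config, path):
        with pytest.raises(sens.ParameterPathError):
            sens.get_param(zambia_config, path)
        with pytest.raises(sens.ParameterPathError):
            sens.set_param(zambia_config, path, 1.0)


class TestDefaultRanges:
    def test_assay_parameters_use_evidence_bounds(self, zambia_config):
        assert sens.default_range(zambia_config, "assays.dbs.capctm.specificity") == (0.720, 0.989)
        assert sens.default_range(zambia_config, "assays.plasma.capctm.sensitivity") == (0.967, 0.993)

    def test_costs_use_half_to_one_and_a_half(self, zambia_config):
        lo, hi = sens.default_range(zambia_config, "unit_costs.psc.consumables")
        assert (lo, hi) == (2.5, 7.5)

    def test_proportions_clipped_at_one(self, zambia_config):
        lo, hi = sens.default_range(zambia_config, "multipliers.high_volume")
        assert hi == 1.0 and lo == pytest.approx(0.4)


class TestOneWay:
    def test_baseline_psc_cost_per_correct(self, zambia_model):
        res = sens.one_way(
            zambia_model, "unit_costs.psc.consumables", 2.5, 7.5,
            "cost_per_correct/plasma_psc", mode="golden",
        )
        assert round(res.baseline, 2) == 31.62

    def test_degenerate_range_returns_baseline_thrice(self, zambia_model):
        res = sens.one_way(
            zambia_model, "unit_costs.psc.consumables", 5.0, 5.0,
            "cost_per_correct/plasma_psc", mode="golden",
        )
        assert res.values[0] == res.values[1] == res.values[2]

    def test_dbs_specificity_monotone(self, zambia_model):
        """Raising DBS specificity lowers the partial-DBS cost per correct result."""
        values = [
            sens.evaluate(
                zambia_model.with_config(
                    sens.set_param(zambia_model.config, "assays.dbs.capctm.specificity", sp)
                ),
                "cost_per_correct/plasma_dbs",
            )
            for sp in (0.89, 0.919, 0.939, 0.959, 0.989)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_sweep_leaves_config_untouched(self, zambia_model):
        before = zambia_model.config.canonical_json()
        sens.one_way(
            zambia_model, "unit_costs.psc.consumables", 1.0, 9.0,
            "system_cost/plasma_psc", mode="golden",
        )
        assert zambia_model.config.canonical_json() == before


class TestTwoWay:
    def test_single_cell_grid_is_baseline(self, zambia_model):
        res = sens.two_way(
            zambia_model,
            "assays.dbs.capctm.sensitivity", "assays.dbs.capctm.specificity",
            [0.948], [0.939],
            "cost_per_correct/plasma_dbs",
        )
        assert res.values.shape == (1, 1)
        assert res.values[0, 0] == pytest.approx(res.baseline)

    def test_matrix_monotone_in_each_axis(self, zambia_model):
        grid_se = [0.90, 0.948, 0.98]
        grid_sp = [0.89, 0.939, 0.98]
        res = sens.two_way(
            zambia_model,
            "assays.dbs.capctm.sensitivity", "assays.dbs.capctm.specificity",
            grid_se, grid_sp,
            "cost_per_correct/plasma_dbs",
        )
        assert (np.diff(res.values, axis=0) < 0).all()
        assert (np.diff(res.values, axis=1) < 0).all()

    def test_row_matches_one_way_grid(self, zambia_model):
        grid = [2.5, 5.0, 7.5]
        mat = sens.two_way(
            zambia_model,
            "unit_costs.psc.consumables", "assays.dbs.capctm.sensitivity",
            grid, [0.948],
            "cost_per_correct/plasma_psc", mode="golden",
        )
        ow = sens.one_way(
            zambia_model, "unit_costs.psc.consumables", 2.5, 7.5,
            "cost_per_correct/plasma_psc", mode="golden",
        )
        assert mat.values[:, 0] == pytest.approx(ow.values)


class TestThreshold:
    def test_linear_root_recovered(self, zambia_model):
        """On a cost metric linear in the kit price the solver matches the closed form."""
        res = sens.threshold(
            zambia_model, "unit_costs.psc.consumables",
            "system_cost/plasma_psc", "system_cost/plasma_dbs",
            bracket=(0.0, 5.0), mode="golden",
        )
        # closed form: dried_tests * (x - x*) = system difference at baseline
        r = zambia_model.fit(mode="golden")
        diff = r.metric("system_cost", "plasma_psc") - r.metric("system_cost", "plasma_dbs")
        x_star = 5.0 - diff / 296_308
        assert res.value == pytest.approx(x_star, abs=1e-6)

    def test_kit_price_equating_cost_per_correct(self, zambia_model):
        res = sens.threshold(
            zambia_model, "unit_costs.psc.consumables",
            "cost_per_correct/plasma_psc", "cost_per_correct/plasma_dbs",
            bracket=(0.0, 5.0), mode="golden",
        )
        assert res.value == pytest.approx(2.72, rel=0.01)
        assert res.residual < 0.005

    def test_kit_price_equating_cost_per_result(self, zambia_model):
        res = sens.threshold(
            zambia_model, "unit_costs.psc.consumables",
            "cost_per_result/plasma_psc", "cost_per_result/plasma_dbs",
            bracket=(0.0, 5.0), mode="golden",
        )
        assert res.value == pytest.approx(1.72, rel=0.01)

    def test_no_sign_change_reports_endpoints(self, zambia_model):
        with pytest.raises(ValueError, match="does not change sign"):
            sens.threshold(
                zambia_model, "unit_costs.psc.consumables",
                "cost_per_correct/plasma_psc", "cost_per_correct/plasma_dbs",
                bracket=(4.0, 5.0), mode="golden",
            )

    def test_dbs_specificity_breakeven_location(self, zambia_model):
        """Deteriorating DBS specificity from 0.94 toward 0.89 makes partial PSC
        cost-neutral; the crossing lies inside that published interval."""
        res = sens.threshold(
            zambia_model, "assays.dbs.capctm.specificity",
            "cost_per_correct/plasma_dbs", "cost_per_correct/plasma_psc",
            bracket=(0.85, 0.99), mode="model",
        )
        assert 0.85 < res.value < 0.96


def test_tornado_frame_sorted_by_swing(zambia_model):
    frame = sens.tornado(
        zambia_model,
        {
            "unit_costs.psc.consumables": (2.5, 7.5),
            "visit_transport.visit_cost": (1.83, 5.48),
            "epi.failure_prevalence": (0.07, 0.28),
        },
        "cost_per_correct/plasma_psc",
    )
    assert list(frame.columns[:3]) == ["parameter", "low_input", "high_input"]
    swings = frame["swing"].tolist()
    assert swings == sorted(swings, reverse=True)
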