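"""One-way sweeps, tornado ranking, threshold bisection, two-way grids."""

import numpy as np
import pytest

from varscreen.cea_metrics import compare_strategies
from varscreen.parameters import get_by_path, with_value
from varscreen.sensitivity import (
    SweepSpec,
    default_sweep_specs,
    one_way_sweep,
    threshold_search,
    tornado,
    two_way_grid,
)


class TestOneWaySweep:
    def test_zero_width_sweep_reproduces_base_case(self, params):
        base = compare_strategies(params)
        points = one_way_sweep(
            SweepSpec("costs.endoscopy", 96.73, 96.73, n_points=3), params
        )
        for _, res in points:
            assert res.incremental_cost == base.incremental_cost
            assert res.incremental_qaly == base.incremental_qaly

    def test_selective_gains_as_endoscopy_price_rises(self, params):
        """The selective arm avoids endoscopies, so its net-benefit margin
        grows strictly with the endoscopy unit price."""
        points = one_way_sweep(
            SweepSpec("costs.endoscopy", 44.64, 178.57, n_points=7), params
        )
        margins = [res.nmb_difference for _, res in points]
        assert all(b > a for a, b in zip(margins, margins[1:]))

    def test_icer_decreasing_while_defined(self, params):
        points = one_way_sweep(
            SweepSpec("costs.endoscopy", 44.64, 60.0, n_points=4), params
        )
        icers = [res.icer for _, res in points]
        assert all(i is not None for i in icers)
        assert all(b < a for a, b in zip(icers, icers[1:]))

    def test_sweep_point_equals_independent_rerun(self, params):
        points = one_way_sweep(
            SweepSpec("accuracy.prevalence_hrv", 0.30, 0.30, n_points=1), params
        )
        rerun = compare_strategies(with_value(params, "accuracy.prevalence_hrv", 0.30))
        assert points[0][1].incremental_cost == rerun.incremental_cost
        assert points[0][1].incremental_qaly == rerun.incremental_qaly

    def test_derived_quantity_sweep_rejected(self, params):
        with pytest.raises(ValueError, match="sweep"):
            one_way_sweep(SweepSpec("p_meet", 0.1, 0.4), params)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="low"):
            SweepSpec("costs.endoscopy", 10.0, 5.0)


class TestTornado:
    def test_spans_match_endpoint_sweeps(self, params):
        specs = [SweepSpec("costs.endoscopy", 44.64, 178.57, n_points=2)]
        frame = tornado(params, specs)
        lo = one_way_sweep(SweepSpec("costs.endoscopy", 44.64, 44.64, 1), params)
        hi = one_way_sweep(SweepSpec("costs.endoscopy", 178.57, 178.57, 1), params)
        expected = abs(hi[0][1].nmb_difference - lo[0][1].nmb_difference)
        assert frame.loc[0, "span"] == pytest.approx(expected)

    def test_zero_width_range_ranked_last(self, params):
        specs = default_sweep_specs(params) + [
            SweepSpec("econ.wtp_per_qaly", 12714.11, 12714.11, 2)
        ]
        frame = tornado(params, specs)
        assert frame.iloc[-1]["parameter"] == "econ.wtp_per_qaly"
        assert frame.iloc[-1]["span"] == 0.0

    def test_endoscopy_cost_among_top_drivers(self, params):
        frame = tornado(params, default_sweep_specs(params))
        assert "costs.endoscopy" in set(frame["parameter"].head(3))

    def test_empty_specs_rejected(self, params):
        with pytest.raises(ValueError, match="at least one"):
            tornado(params, [])


class TestThresholdSearch:
    def test_linear_toy_criterion_finds_root(self, params):
        def margin(p):
            return get_by_path(p, "costs.endoscopy") - 100.0

        res = threshold_search("costs.endoscopy", margin, (1.0, 400.0), params)
        assert res.threshold_value == pytest.approx(100.0, abs=0.01)

    def test_bracket_invariance(self, params):
        def margin(p):
            return get_by_path(p, "costs.endoscopy") - 100.0

        a = threshold_search("costs.endoscopy", margin, (50.0, 150.0), params)
        b = threshold_search("costs.endoscopy", margin, (99.0, 350.0), params)
        assert a.threshold_value == pytest.approx(b.threshold_value, abs=0.02)

    def test_monotone_bracket_raises(self, params):
        def margin(p):
            return 1.0

        with pytest.raises(ValueError, match="monotone"):
            threshold_search("costs.endoscopy", margin, (1.0, 400.0), params)

    def test_cost_break_even_flips_criterion(self, params):
        """The bisection point genuinely separates the cheaper-arm regimes."""
        res = threshold_search(
            "costs.endoscopy", "selective_cost_le_universal", (1.0, 400.0), params
        )
        below = compare_strategies(
            with_value(params, "costs.endoscopy", res.threshold_value - 1.0)
        )
        above = compare_strategies(
            with_value(params, "costs.endoscopy", res.threshold_value + 1.0)
        )
        assert below.incremental_cost > 0.0  # selective costlier below
        assert above.incremental_cost < 0.0  # selective cheaper above


class TestTwoWayGrid:
    def test_single_point_grid_base_case_cost_effective(self, params):
        grid = two_way_grid(
            "accuracy.sensitivity",
            "accuracy.specificity",
            np.array([0.97]),
            np.array([0.32]),
            params,
        )
        assert grid.shape == (1, 1)
        assert bool(grid.iloc[0, 0])

    def test_axes_and_shape(self, params):
        grid = two_way_grid(
            "accuracy.sensitivity",
            "accuracy.specificity",
            np.linspace(0.90, 0.98, 3),
            np.linspace(0.26, 0.39, 4),
            params,
        )
        assert grid.shape == (3, 4)
        assert grid.index.name == "accuracy.sensitivity"
        assert grid.columns.name == "accuracy.specificity"
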