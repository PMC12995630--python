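"""Closed-form conv costs, model accounting and the budget calibration."""

from fractions import Fraction

import numpy as np
import pytest

from mdpcnet.complexity import (BudgetSpec, CalibrationError, CostQuery,
                                DatasetShape, calibrate_reference_config,
                                complexity_report, cost_dpc, cost_ratio,
                                cost_standard, count_flops, count_macs,
                                count_params)
from mdpcnet.config import ModelConfig
from mdpcnet.model import MdpcNet


class TestClosedFormCosts:
    def test_standard_conv_worked_example(self):
        q = CostQuery(K=3, H=11, W=11, C_in=8, C_out=16)
        assert cost_standard(q) == 139_392

    def test_dpc_worked_example(self):
        q = CostQuery(K=3, H=11, W=11, C_in=8, C_out=16)
        assert cost_dpc(q) == (9 + 16) * 121 * 8 == 24_200

    def test_identity_query(self):
        assert cost_standard(CostQuery(1, 1, 1, 1, 1)) == 1

    def test_linearity_in_output_channels(self):
        q1 = CostQuery(3, 7, 7, 4, 8)
        q2 = CostQuery(3, 7, 7, 4, 16)
        assert cost_standard(q2) == 2 * cost_standard(q1)

    def test_dpc_decomposes_into_stages(self):
        q = CostQuery(5, 9, 8, 6, 12)
        depthwise = 25 * 9 * 8 * 6
        pointwise = 9 * 8 * 6 * 12
        assert cost_dpc(q) == depthwise + pointwise

    def test_pointwise_degenerate_ratio(self):
        # K = 1, C_out = 1: the separable form costs twice the standard conv
        assert cost_ratio(1, 1) == pytest.approx(2.0)

    @pytest.mark.parametrize("k,c_out,expected", [
        (3, 16, 25 / 144), (3, 9, 2 / 9),
    ])
    def test_ratio_values(self, k, c_out, expected):
        assert cost_ratio(k, c_out) == pytest.approx(expected)

    def test_ratio_equals_cost_quotient_on_200_random_queries(self):
        """H, W and C_in cancel exactly (checked in rational arithmetic)."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            q = CostQuery(K=int(rng.integers(1, 8)), H=int(rng.integers(1, 30)),
                          W=int(rng.integers(1, 30)),
                          C_in=int(rng.integers(1, 64)),
                          C_out=int(rng.integers(1, 128)))
            exact = Fraction(cost_dpc(q), cost_standard(q))
            assert exact == Fraction(1, q.C_out) + Fraction(1, q.K ** 2)
            # separable form is cheaper whenever K > 1 and C_out > 1
            if q.K > 1 and q.C_out > 1:
                assert cost_dpc(q) < cost_standard(q)


class TestModelAccounting:
    def small_cfg(self, **kw):
        base = dict(n_bands=10, n_classes=4, patch_size=5, stage_width=2,
                    pyramid_width=6, model_dim=8, n_heads=2, mlp_hidden=4,
                    n_tokens=2)
        base.update(kw)
        return ModelConfig(**base)

    @pytest.mark.parametrize("kw", [
        {}, {"fusion": "plain_concat_linear"},
        {"use_1d": False}, {"use_2d": False, "use_3d": False},
    ])
    def test_analytic_count_matches_built_enumeration(self, rng, kw):
        cfg = self.small_cfg(**kw)
        model = MdpcNet(cfg, rng)
        assert count_params(cfg) == model.n_params()

    def test_reference_shape_counts_match_built_models(self, rng):
        for bands, classes in ((256, 16), (270, 7)):
            cfg = ModelConfig(n_bands=bands, n_classes=classes,
                              stage_width=21, pyramid_width=468)
            assert count_params(cfg) == MdpcNet(cfg, rng).n_params()

    def test_lone_conv_flop_example(self):
        # a 3x3 "same" conv on 11x11 with C_in=2, C_out=4: 8,712 MACs
        assert cost_standard(CostQuery(3, 11, 11, 2, 4)) == 8_712
        # under the 2-FLOPs-per-MAC convention that is 17,424 FLOPs
        assert 2 * cost_standard(CostQuery(3, 11, 11, 2, 4)) == 17_424

    def test_flops_are_macs_times_convention(self):
        cfg = self.small_cfg()
        assert count_flops(cfg, flops_per_mac=2) == 2 * count_macs(cfg)
        assert count_flops(cfg, flops_per_mac=1) == count_macs(cfg)

    def test_dilation_change_leaves_count_unchanged(self):
        from mdpcnet.config import PdcSchedule

        a = self.small_cfg(schedule=PdcSchedule(printed_rates=(0, 1, 2, 5)))
        b = self.small_cfg(schedule=PdcSchedule(printed_rates=(0, 2, 4, 8)))
        assert count_params(a) == count_params(b)

    def test_per_class_head_sensitivity(self):
        a = self.small_cfg(n_classes=4)
        b = self.small_cfg(n_classes=5)
        assert count_params(b) - count_params(a) == a.model_dim + 1

    def test_band_sensitivity_positive(self):
        a = ModelConfig(n_bands=256, n_classes=7, stage_width=21,
                        pyramid_width=468)
        b = ModelConfig(n_bands=270, n_classes=7, stage_width=21,
                        pyramid_width=468)
        assert count_params(b) > count_params(a)

    def test_report_totals_consistent(self):
        cfg = self.small_cfg()
        rep = complexity_report(cfg)
        assert rep["total_params"] == sum(r["params"] for r in rep["layers"])
        assert rep["total_flops"] == 2 * sum(r["macs"] for r in rep["layers"])


class TestCalibration:
    def test_single_budget_single_width_monotone(self):
        # params are strictly increasing in stage width, so a 1-D scan finds
        # the unique width meeting a tolerance or reports the best miss
        cfg_of = lambda w: ModelConfig(n_bands=64, n_classes=5, stage_width=w,
                                       pyramid_width=48)
        params = [count_params(cfg_of(w)) for w in range(2, 30)]
        assert all(b > a for a, b in zip(params, params[1:]))
        target = params[10] / 1e6
        spec = BudgetSpec(shapes=(DatasetShape("one", 64, 5, target, 0.0),),
                          tolerance_params_M=1e-9)
        res = calibrate_reference_config(spec, stage_widths=range(2, 30),
                                         pyramid_widths=[48])
        assert res.stage_width == 12

    def test_widened_tolerance_nests(self):
        strict = BudgetSpec(tolerance_params_M=0.0005)
        wide = BudgetSpec(tolerance_params_M=0.01)
        res_strict = calibrate_reference_config(strict)
        res_wide = calibrate_reference_config(wide)
        assert res_wide.max_abs_dev_M <= wide.tolerance_params_M
        assert res_strict.max_abs_dev_M <= strict.tolerance_params_M

    def test_empty_search_space_rejected(self):
        with pytest.raises(CalibrationError, match="empty"):
            calibrate_reference_config(stage_widths=[], pyramid_widths=[3])

    def test_unreachable_budget_reports_best_miss(self):
        spec = BudgetSpec(shapes=(DatasetShape("x", 64, 5, 99.0, 0.0),),
                          tolerance_params_M=1e-6)
        with pytest.raises(CalibrationError, match="best miss"):
            calibrate_reference_config(spec, stage_widths=[4],
                                       pyramid_widths=[48])

    def test_full_three_shape_calibration_within_tolerance(self):
        res = calibrate_reference_config()
        assert res.max_abs_dev_M <= 0.0005
        for entry in res.per_dataset.values():
            assert entry["params_M"] == entry["printed_params_M"]
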