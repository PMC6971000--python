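"""FOC normalization, the comparison decision tree, 4PL fits and EC50 summary."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sldt import (
    FourPLModel,
    compare_groups,
    compute_foc,
    fit_4pl,
    fourpl_curve,
    summarize_ec50,
)
from sldt.doseresponse import (
    CI_UNDEFINED,
    DEGENERATE_VARIANCE,
    SMALL_GROUP,
    dunnett_pvalues,
)


class TestComputeFOC:
    def test_basic_ratio(self):
        recs = compute_foc([50.0], [90.0, 100.0, 110.0])
        assert recs[0].foc == pytest.approx(0.5)

    def test_control_group_mean_is_exactly_one(self):
        ctrl = [88.0, 103.0, 121.0, 95.0]
        recs = compute_foc(ctrl, ctrl)
        assert np.mean([r.foc for r in recs]) == pytest.approx(1.0, abs=1e-12)

    def test_stimulation_above_one_allowed(self):
        recs = compute_foc([300.0], [100.0, 100.0])
        assert recs[0].foc == pytest.approx(3.0)

    def test_nonpositive_control_mean_rejected(self):
        with pytest.raises(ValueError):
            compute_foc([1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            compute_foc([1.0], [])

    @given(
        k=st.floats(min_value=1e-3, max_value=1e3),
        vals=st.lists(st.floats(1.0, 1e4), min_size=1, max_size=6),
        ctrl=st.lists(st.floats(1.0, 1e4), min_size=2, max_size=6),
    )
    @settings(deadline=None, max_examples=60)
    def test_scale_invariance(self, k, vals, ctrl):
        base = [r.foc for r in compute_foc(vals, ctrl)]
        scaled = [r.foc for r in compute_foc([v * k for v in vals], [c * k for c in ctrl])]
        assert scaled == pytest.approx(base, rel=1e-9)


class TestCompareGroups:
    def test_identical_groups_degenerate(self):
        res = compare_groups({0: [1.0, 1.0, 1.0], 1: [1.0, 1.0, 1.0]})
        assert DEGENERATE_VARIANCE in res.qc_flags
        assert res.p_values[1] == 1.0

    def test_normal_data_routes_to_dunnett(self):
        rng = np.random.default_rng(10)
        groups = {c: rng.normal(1.0, 0.1, 5) for c in (0, 1, 2, 3)}
        res = compare_groups(groups)
        assert res.test_used == "ANOVA+Dunnett"
        assert set(res.p_values) == {1, 2, 3}
        assert all(0.0 <= p <= 1.0 for p in res.p_values.values())

    def test_two_groups_route_to_t_test(self):
        rng = np.random.default_rng(11)
        res = compare_groups({0: rng.normal(1, 0.1, 6), 1: rng.normal(1, 0.1, 6)})
        assert res.test_used == "t-test"

    def test_unequal_variance_routes_to_ranks(self):
        rng = np.random.default_rng(12)
        groups = {
            0: rng.normal(1.0, 0.001, 6),
            1: rng.normal(1.0, 0.001, 6),
            2: rng.normal(1.0, 5.0, 6),
        }
        res = compare_groups(groups)
        assert res.test_used == "KW+Dunn"

    def test_singleton_group_falls_to_ranks_with_note(self):
        rng = np.random.default_rng(13)
        groups = {0: rng.normal(1, 0.1, 4), 1: [0.9], 2: rng.normal(1, 0.1, 4)}
        res = compare_groups(groups)
        assert SMALL_GROUP in res.qc_flags
        assert res.test_used == "KW+Dunn"

    def test_large_shift_detected_with_high_power(self):
        """A 5-sd shifted group (n = 3) is detected essentially always.

        Monte-Carlo power check: with the shifted-group t-statistic around
        6 at 8 df, the Dunnett-adjusted p-value is typically ~1e-3, and a
        rejection at alpha 0.05 is near-certain.
        """
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(100):
            ctrl = rng.normal(1.0, 0.2, 3)
            treated = [rng.normal(1.0, 0.2, 3), rng.normal(0.0, 0.2, 3)]
            ps.append(dunnett_pvalues(treated, ctrl, np.random.default_rng(1))[1])
        assert np.median(ps) < 1e-2
        assert np.mean(np.asarray(ps) <= 0.05) >= 0.95


class TestFourPL:
    CONCS = np.array([0.05, 0.15, 0.5, 1.2, 3.0, 10.0, 40.0])

    def test_recovers_generating_parameters_noiselessly(self):
        y = fourpl_curve(self.CONCS, 0.0, 1.0, 1.2, 2.0)
        fit = fit_4pl(self.CONCS, y)
        assert fit.converged
        assert fit.ec50 == pytest.approx(1.2, rel=0.01)
        assert fit.hill == pytest.approx(2.0, rel=0.01)

    def test_stimulator_with_negative_hill(self):
        y = fourpl_curve(self.CONCS, 0.2, 1.0, 2.0, -1.5)
        fit = fit_4pl(self.CONCS, y)
        assert fit.converged
        assert fit.ec50 == pytest.approx(2.0, rel=0.01)
        assert fit.hill == pytest.approx(-1.5, rel=0.05)

    def test_flat_data_does_not_converge(self):
        fit = fit_4pl(self.CONCS, np.ones_like(self.CONCS))
        assert not fit.converged
        assert math.isnan(fit.ec50)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_4pl([1.0, 2.0, 4.0], [1.0, 0.6, 0.2])

    def test_concentration_scale_equivariance(self):
        y = fourpl_curve(self.CONCS, 0.1, 1.0, 1.2, 1.5)
        base = fit_4pl(self.CONCS, y)
        scaled = fit_4pl(self.CONCS * 1e3, y)
        assert scaled.ec50 / base.ec50 == pytest.approx(1e3, rel=1e-6)

    def test_anchored_top(self):
        y = fourpl_curve(self.CONCS, 0.0, 1.0, 1.2, 2.0)
        fit = FourPLModel(self.CONCS, y).fit(anchor_top=1.0)
        assert fit.top == 1.0
        assert fit.ec50 == pytest.approx(1.2, rel=0.01)

    def test_summary_and_dataframe_constructor(self):
        import pandas as pd

        df = pd.DataFrame(
            {"concentration": self.CONCS, "foc": fourpl_curve(self.CONCS, 0, 1, 1.2, 2)}
        )
        fit = FourPLModel.from_dataframe(df, experiment_id="exp1").fit()
        text = fit.summary()
        assert "ec50" in text and "exp1" in text


class TestSummarizeEC50:
    def test_identical_values_returned_exactly(self):
        s = summarize_ec50([2.0, 2.0, 2.0])
        assert s.geomean_ec50 == pytest.approx(2.0)
        assert s.ci_low == pytest.approx(2.0)
        assert s.ci_high == pytest.approx(2.0)

    def test_geometric_mean_of_one_and_four_is_two(self):
        assert summarize_ec50([1.0, 4.0]).geomean_ec50 == pytest.approx(2.0)

    def test_hand_computed_three_experiment_summary(self):
        # oracle via logs: geomean = exp(mean(ln{0.8, 1.2, 1.0})) = 0.986485,
        # CI = exp(mean ± t(0.975, 2) * sd/sqrt(3)) = (0.59565, 1.63374)
        s = summarize_ec50([0.8, 1.2, 1.0])
        assert s.geomean_ec50 == pytest.approx(0.986485, rel=1e-5)
        assert s.ci_low == pytest.approx(0.59565, rel=1e-4)
        assert s.ci_high == pytest.approx(1.63374, rel=1e-4)

    def test_single_experiment_has_undefined_ci(self):
        s = summarize_ec50([3.3])
        assert s.geomean_ec50 == pytest.approx(3.3)
        assert math.isnan(s.ci_low) and math.isnan(s.ci_high)
        assert CI_UNDEFINED in s.qc_flags

    def test_no_converged_fits_is_an_error(self):
        bad = fit_4pl(
            [0.1, 0.3, 1.0, 3.0, 10.0], [1.0, 1.0, 1.0, 1.0, 1.0]
        )  # flat -> non-converged
        with pytest.raises(ValueError):
            summarize_ec50([bad])

    @given(x=st.floats(min_value=1e-3, max_value=1e3), n=st.integers(1, 6))
    @settings(deadline=None, max_examples=40)
    def test_copies_of_x_return_x(self, x, n):
        assert summarize_ec50([x] * n).geomean_ec50 == pytest.approx(x, rel=1e-9)
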