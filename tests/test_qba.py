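"""Selection-bias parameters, triangular prior, and the Monte Carlo chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from selectqba.qba import (
    QBAInputs,
    SelectionProportions,
    derive_seed,
    or_select,
    or_select_from_benchmark,
    or_select_from_proportions,
    qba_batch,
    qba_simulate,
    sample_triangular,
    se_from_ci,
)


class TestSeFromCI:
    def test_published_interval(self):
        assert se_from_ci(3.27, 7.40) == pytest.approx(0.20834, abs=5e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        k=st.floats(0.01, 50),
        se=st.floats(0.01, 2.0),
    )
    def test_inverts_ci_construction(self, k, se):
        hi = k * np.exp(2 * 1.959964 * se)
        assert se_from_ci(k, hi) == pytest.approx(se, rel=1e-6)

    def test_degenerate_interval_errors(self):
        with pytest.raises(ValueError):
            se_from_ci(2.0, 2.0)
        with pytest.raises(ValueError):
            se_from_ci(-1.0, 2.0)


class TestOrSelect:
    def test_benchmark_worked_example(self):
        """Control-sample rate 8.00 over living-benchmark rate 4.67."""
        val = or_select_from_benchmark(8.00, 4.67)
        assert round(val, 2) == 1.71
        assert val == pytest.approx(1.713, abs=5e-4)

    def test_nondifferential_selection_is_unity(self):
        sel = SelectionProportions(s_control_1=0.3, s_control_0=0.3)
        assert or_select_from_proportions(sel) == pytest.approx(1.0)

    def test_full_four_proportion_form(self):
        sel = SelectionProportions(
            s_case_1=0.5, s_case_0=1.0, s_control_1=1.0, s_control_0=1.0
        )
        assert or_select_from_proportions(sel) == pytest.approx(2.0)

    def test_all_cases_selected_reduces_to_control_ratio(self):
        sel = SelectionProportions(s_control_1=0.4, s_control_0=0.2)
        assert or_select(sel) == pytest.approx(2.0)

    def test_zero_benchmark_rate_errors(self):
        with pytest.raises(ValueError):
            or_select_from_benchmark(8.0, 0.0)

    def test_proportions_validated(self):
        with pytest.raises(ValueError):
            SelectionProportions(s_control_1=1.5, s_control_0=0.5)


class TestTriangular:
    def test_symmetric_mean_and_variance(self):
        a, c, b = 1.368, 1.71, 2.052
        draws = sample_triangular(c, a, b, 1_000_000, seed=0)
        assert draws.min() >= a and draws.max() <= b
        assert draws.mean() == pytest.approx((a + b + c) / 3, abs=2e-3)
        var = (a**2 + b**2 + c**2 - a * b - a * c - b * c) / 18
        assert var == pytest.approx(0.01949, abs=5e-5)
        assert draws.var() == pytest.approx(var, rel=0.01)

    def test_degenerate_point_mass(self):
        draws = sample_triangular(1.71, 1.71, 1.71, 100, seed=0)
        assert (draws == 1.71).all()

    def test_invalid_limits_error(self):
        with pytest.raises(ValueError):
            sample_triangular(1.0, 2.0, 0.5, 10)
        with pytest.raises(ValueError):
            sample_triangular(5.0, 1.0, 2.0, 10)


class TestQbaSimulate:
    def test_degenerate_inputs_pass_through(self):
        """No bias and no random error: every draw is the observed OR."""
        inp = QBAInputs(
            4.92, 3.27, 7.40, or_select_mode=1.0, se_ln_or=0.0,
            rel_lower=0.0, rel_upper=0.0, n_iter=2000, seed=1,
        )
        res = qba_simulate(inp, keep_draws=True)
        np.testing.assert_allclose(res.draws, 4.92)
        assert res.median == res.si_low == res.si_high == pytest.approx(4.92)

    def test_unit_bias_parameter_keeps_median(self):
        inp = QBAInputs(4.92, 3.27, 7.40, or_select_mode=1.0, seed=2)
        res = qba_simulate(inp)
        assert res.median == pytest.approx(4.92, rel=0.02)
        # triangular spread widens the interval beyond the original CI
        assert res.si_low < 3.27 and res.si_high > 7.40

    def test_median_converges_to_adjusted_point(self):
        """Symmetric triangular and median-zero noise: the median tends to
        or_observed * or_select_mode (0.5% at 5e5 iterations)."""
        inp = QBAInputs(4.92, 3.27, 7.40, or_select_mode=1.71, n_iter=500_000,
                        seed=3)
        res = qba_simulate(inp)
        assert res.median == pytest.approx(4.92 * 1.71, rel=0.005)

    def test_bit_reproducible_under_fixed_seed(self):
        inp = QBAInputs(2.0, 1.5, 2.7, or_select_mode=1.2, n_iter=5000, seed=42)
        r1 = qba_simulate(inp, keep_draws=True)
        r2 = qba_simulate(inp, keep_draws=True)
        assert (r1.draws == r2.draws).all()
        assert (r1.median, r1.si_low, r1.si_high) == (
            r2.median, r2.si_low, r2.si_high,
        )

    def test_si_ordering_invariant(self):
        res = qba_simulate(QBAInputs(1.4, 1.05, 1.88, 0.8, seed=8, n_iter=4000))
        assert res.si_low <= res.median <= res.si_high
        assert res.si_low > 0

    def test_monotone_in_bias_and_observed(self):
        base = dict(ci_low=1.5, ci_high=2.7, n_iter=20_000, seed=5)
        meds_mode = [
            qba_simulate(QBAInputs(2.0, or_select_mode=m, **base)).median
            for m in (0.8, 1.0, 1.3, 1.7)
        ]
        assert meds_mode == sorted(meds_mode)
        meds_or = [
            qba_simulate(QBAInputs(o, or_select_mode=1.2, **base)).median
            for o in (1.6, 2.0, 2.4)
        ]
        assert meds_or == sorted(meds_or)

    def test_scale_equivariance(self):
        """Multiplying the observed OR by c multiplies all summaries by c
        (same seed gives identical relative draws)."""
        base = dict(or_select_mode=1.3, se_ln_or=0.2, n_iter=10_000, seed=6)
        r1 = qba_simulate(QBAInputs(2.0, 1.5, 2.7, **base))
        r2 = qba_simulate(QBAInputs(6.0, 4.5, 8.1, **base))
        assert r2.median == pytest.approx(3 * r1.median, rel=1e-9)
        assert r2.si_low == pytest.approx(3 * r1.si_low, rel=1e-9)
        assert r2.si_high == pytest.approx(3 * r1.si_high, rel=1e-9)

    def test_too_few_iterations_refused(self):
        with pytest.raises(ValueError, match="n_iter"):
            QBAInputs(2.0, 1.5, 2.7, 1.2, n_iter=500)

    def test_invalid_inputs_refused(self):
        with pytest.raises(ValueError):
            QBAInputs(2.0, 2.5, 2.7, 1.2)  # or outside CI
        with pytest.raises(ValueError):
            QBAInputs(-1.0, 0.5, 2.0, 1.2)


class TestQbaBatch:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["exposure", "or_observed", "ci_low", "ci_high",
                     "or_select_mode"],
        )

    def test_batch_of_one_reduces_to_simulate(self):
        table = self._table([("a", 4.92, 3.27, 7.40, 1.71)])
        batch = qba_batch(table, n_iter=5000, master_seed=9)
        single = qba_simulate(
            QBAInputs(4.92, 3.27, 7.40, 1.71, n_iter=5000,
                      seed=derive_seed(9, "a"), exposure="a")
        )
        assert batch["median"].iloc[0] == single.median
        assert batch["si_low"].iloc[0] == single.si_low

    def test_seed_derivation_order_independent(self):
        rows = [("a", 2.0, 1.5, 2.7, 1.2), ("b", 1.4, 1.05, 1.88, 0.9)]
        fwd = qba_batch(self._table(rows), n_iter=2000, master_seed=3)
        rev = qba_batch(self._table(rows[::-1]), n_iter=2000, master_seed=3)
        merged = fwd.set_index("exposure").join(
            rev.set_index("exposure"), rsuffix="_rev"
        )
        assert (merged["median"] == merged["median_rev"]).all()

    def test_identical_inputs_distinct_seeds(self):
        rows = [("a", 2.0, 1.5, 2.7, 1.2), ("b", 2.0, 1.5, 2.7, 1.2)]
        batch = qba_batch(self._table(rows), n_iter=50_000, master_seed=1)
        m = batch["median"]
        assert m.iloc[0] != m.iloc[1]  # draws differ
        assert m.iloc[0] == pytest.approx(m.iloc[1], rel=0.02)  # but agree

    def test_duplicate_labels_error(self):
        rows = [("a", 2.0, 1.5, 2.7, 1.2), ("a", 1.4, 1.05, 1.88, 0.9)]
        with pytest.raises(ValueError, match="duplicate"):
            qba_batch(self._table(rows), n_iter=2000)

    def test_mode_below_one_adjusts_downward(self):
        rows = [("assault", 0.54, 0.32, 0.92, 0.7)]
        batch = qba_batch(self._table(rows), n_iter=20_000, master_seed=2)
        assert batch["median"].iloc[0] < 0.54

    def test_forest_plot_renders(self, tmp_path):
        from selectqba.qba import forest_plot

        rows = [("a", 2.0, 1.5, 2.7, 1.2), ("b", 1.4, 1.05, 1.88, 0.9)]
        batch = qba_batch(self._table(rows), n_iter=2000, master_seed=3)
        out = tmp_path / "forest.svg"
        forest_plot(batch, out)
        assert out.stat().st_size > 0


def test_derive_seed_stable_and_bounded():
    s1 = derive_seed(17, "mental illness")
    assert s1 == derive_seed(17, "mental illness")
    assert 0 <= s1 < 2**31
    assert s1 != derive_seed(17, "pain")
    assert s1 != derive_seed(18, "mental illness")
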