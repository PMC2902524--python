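import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from regged.calibration import (
    LinearMap,
    adjustment_factors,
    aggregate_profile,
    apply_map,
    sorted_line_fit,
    symmetric_calibration,
)
from regged.io import ExpressionMatrix
from regged.simulate import SimulationConfig, simulate_compartment_pair


def _ols_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form normal-equations OLS, independent of scipy."""
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def _profile(values, ids=None) -> pd.Series:
    values = np.asarray(values, dtype=float)
    ids = ids or [f"PS{i}" for i in range(len(values))]
    return pd.Series(values, index=ids)


class TestAggregateProfile:
    def test_single_sample_is_identity(self):
        m = ExpressionMatrix(
            data=pd.DataFrame({"s1": [2.0, 5.0]}, index=["a", "b"]), compartment_label="g"
        )
        np.testing.assert_array_equal(aggregate_profile(m).to_numpy(), [2.0, 5.0])

    def test_row_means(self, small_pair):
        glom, _, _ = small_pair
        expected = glom.values.sum(axis=1) / glom.shape[1]  # independent summation
        np.testing.assert_allclose(aggregate_profile(glom).to_numpy(), expected)
        assert list(aggregate_profile(glom).index) == glom.probeset_ids


class TestSortedLineFit:
    def test_identical_profiles_give_identical_fits(self):
        p = _profile([3.0, 1.0, 2.0, 5.0])
        fit_g, fit_t = sorted_line_fit(p, p.copy(), sort_by="tub")
        assert fit_g == fit_t

    def test_matches_normal_equations_oracle(self, rng):
        values_g = rng.normal(7, 2, size=500)
        values_t = rng.normal(6, 2, size=500)
        pg, pt = _profile(values_g), _profile(values_t)
        fit_g, fit_t = sorted_line_fit(pg, pt, sort_by="tub")
        order = np.argsort(values_t, kind="stable")
        x = np.arange(1, 501, dtype=float)
        for fit, y in ((fit_g, values_g[order]), (fit_t, values_t[order])):
            slope, intercept = _ols_oracle(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-9)
            assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_affine_image_recovers_slope_ratio(self):
        # tub an exact affine image of glom: ratio of fitted slopes == a
        rng = np.random.default_rng(0)
        glom = _profile(np.sort(rng.normal(7, 2, 200)))
        a, b = 0.8, 1.5
        tub = (glom - b) / a
        fit_g, fit_t = sorted_line_fit(glom, tub, sort_by="tub")
        assert fit_g.slope / fit_t.slope == pytest.approx(a, rel=1e-9)

    def test_ties_broken_by_probeset_id(self):
        # equal sort keys: order must follow the probeset ID, deterministically
        pg = _profile([1.0, 2.0, 3.0], ids=["c", "b", "a"])
        pt = _profile([5.0, 5.0, 5.0], ids=["c", "b", "a"])
        fit1 = sorted_line_fit(pg, pt, sort_by="tub")
        fit2 = sorted_line_fit(pg.sort_index(), pt.sort_index(), sort_by="tub")
        assert fit1 == fit2

    def test_mismatched_probesets_error(self):
        with pytest.raises(ValueError, match="symmetric difference"):
            sorted_line_fit(_profile([1, 2], ids=["a", "b"]), _profile([1, 2], ids=["a", "c"]),
                            sort_by="tub")

    def test_fewer_than_two_probesets_error(self):
        with pytest.raises(ValueError):
            sorted_line_fit(_profile([1.0]), _profile([1.0]), sort_by="tub")


class TestAdjustmentFactors:
    def test_slope_ratio_and_intercept_difference(self):
        adj = adjustment_factors(LinearMap(2.0, 5.0), LinearMap(4.0, 3.0))
        assert adj == LinearMap(0.5, 2.0)

    def test_identity_for_identical_fits(self):
        adj = adjustment_factors(LinearMap(0.2, 1.0), LinearMap(0.2, 1.0))
        assert adj == LinearMap(1.0, 0.0)

    def test_zero_tub_slope_rejected(self):
        with pytest.raises(ZeroDivisionError):
            adjustment_factors(LinearMap(1.0, 0.0), LinearMap(0.0, 1.0))

    def test_invariant_to_common_abscissa_rescaling(self, rng):
        # multiplying the shared abscissa by any c > 0 rescales both OLS
        # slopes identically, leaving the ratio (and the intercept
        # difference) unchanged
        y_g = np.sort(rng.normal(7, 2, 300))
        y_t = np.sort(rng.normal(6, 1.5, 300))
        x = np.arange(1, 301, dtype=float)
        for c in (0.01, 1.0, 37.5):
            fits = [_ols_oracle(c * x, y) for y in (y_g, y_t)]
            adj = adjustment_factors(LinearMap(*fits[0]), LinearMap(*fits[1]))
            base = adjustment_factors(
                LinearMap(*_ols_oracle(x, y_g)), LinearMap(*_ols_oracle(x, y_t))
            )
            assert adj.slope == pytest.approx(base.slope, rel=1e-9)
            assert adj.intercept == pytest.approx(base.intercept, abs=1e-9)


class TestSymmetricCalibration:
    def test_final_map_is_mean_of_passes(self, small_pair):
        glom, tub, _ = small_pair
        res = symmetric_calibration(aggregate_profile(glom), aggregate_profile(tub))
        assert res.final_map.slope == pytest.approx(
            (res.pass1.adjustment.slope + res.pass2.adjustment.slope) / 2
        )
        assert res.final_map.intercept == pytest.approx(
            (res.pass1.adjustment.intercept + res.pass2.adjustment.intercept) / 2
        )

    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=3, max_size=40).filter(
            lambda v: max(v) - min(v) > 1e-6
        )
    )
    def test_self_calibration_is_identity(self, values):
        p = _profile(values)
        res = symmetric_calibration(p, p.copy())
        assert res.final_map.slope == pytest.approx(1.0, abs=1e-9)
        assert res.final_map.intercept == pytest.approx(0.0, abs=1e-7)

    def test_additive_shift_recovered_exactly(self):
        # tub = glom - b (a = 1, zero noise): final map must be (1, b)
        rng = np.random.default_rng(5)
        glom = _profile(rng.normal(7, 2, 1000))
        b = 1.17905
        tub = glom - b
        res = symmetric_calibration(glom, tub)
        assert res.final_map.slope == pytest.approx(1.0, abs=1e-6)
        assert res.final_map.intercept == pytest.approx(b, abs=1e-6)
        adjusted = apply_map(res.final_map, tub)
        np.testing.assert_allclose(adjusted.to_numpy(), glom.to_numpy(), atol=1e-6)


class TestApplyMap:
    def test_identity_map_preserves_profile(self):
        p = _profile([1.0, 2.0, 3.0])
        pd.testing.assert_series_equal(apply_map(LinearMap(1.0, 0.0), p), p)

    def test_final_published_map_on_value_ten(self):
        p = _profile([10.0])
        assert apply_map(LinearMap(0.9392425, 1.17905), p).iloc[0] == pytest.approx(10.571475)

    def test_apply_then_inverse_round_trips(self, rng):
        p = _profile(rng.normal(7, 2, 100))
        m = LinearMap(0.9392425, 1.17905)
        back = apply_map(m.inverted(), apply_map(m, p))
        np.testing.assert_allclose(back.to_numpy(), p.to_numpy(), atol=1e-9)

    def test_non_invertible_map_rejected(self):
        with pytest.raises(ZeroDivisionError):
            LinearMap(0.0, 1.0).inverted()
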