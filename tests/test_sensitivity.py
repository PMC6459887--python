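"""Leave-one-out and MR-Egger: examples, closed-form oracle, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivmr import (
    egger_regression,
    ivw_pool,
    leave_one_out,
    orient_exposure_positive,
    wald_ratio,
)

from conftest import make_instrument, random_instruments


def wls_normal_equations(x, y, w):
    """Independent closed-form weighted least squares (free intercept).

    Solves the 2x2 weighted normal equations directly and returns
    (intercept, slope, se_intercept, se_slope) with the multiplicative
    overdispersion convention (residual SE floored at 1).
    """
    x, y, w = map(np.asarray, (x, y, w))
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = y - intercept - slope * x
    scale = (w * resid**2).sum() / (len(x) - 2)
    sigma = max(1.0, math.sqrt(scale))
    se_intercept = sigma * math.sqrt(swxx / det)
    se_slope = sigma * math.sqrt(sw / det)
    return intercept, slope, se_intercept, se_slope


class TestOrientation:
    def test_negative_exposure_flipped_positive(self):
        inst = make_instrument(beta_exposure=-0.1, beta_outcome=-0.02)
        (out,) = orient_exposure_positive([inst])
        assert out.beta_exposure == 0.1
        assert out.beta_outcome == 0.02
        assert out.flipped != inst.flipped

    def test_positive_set_unchanged(self):
        instruments = [make_instrument(variant_id=f"rs{i}", beta_exposure=0.1 * (i + 1))
                       for i in range(3)]
        assert orient_exposure_positive(instruments) == instruments

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 10))
    def test_wald_ratio_unchanged_by_orientation(self, seed, k):
        rng = np.random.default_rng(seed)
        instruments = random_instruments(rng, k)
        for before, after in zip(instruments, orient_exposure_positive(instruments)):
            wb, wa = wald_ratio(before), wald_ratio(after)
            assert wb.ratio == pytest.approx(wa.ratio, rel=1e-14)
            assert wb.se == pytest.approx(wa.se, rel=1e-14)


class TestLeaveOneOut:
    def test_loo_matches_independent_subset_pooling(self):
        instruments = [
            make_instrument(variant_id="rsA", beta_exposure=0.10, beta_outcome=0.012,
                            se_outcome=0.010),
            make_instrument(variant_id="rsB", beta_exposure=0.08, beta_outcome=0.009,
                            se_outcome=0.012),
            make_instrument(variant_id="rsC", beta_exposure=0.06, beta_outcome=0.007,
                            se_outcome=0.015),
        ]
        results = leave_one_out(instruments, model="fixed")
        assert [r.omitted_variant for r in results] == ["rsA", "rsB", "rsC"]
        for idx, res in enumerate(results):
            subset = instruments[:idx] + instruments[idx + 1:]
            oracle = ivw_pool([wald_ratio(i) for i in subset], model="fixed")
            assert res.pooled.beta == pytest.approx(oracle.beta, rel=1e-14)
            assert res.pooled.se == pytest.approx(oracle.se, rel=1e-14)
            assert res.pooled.n_instruments == len(instruments) - 1

    def test_table1_loo_or_range(self, table1_instruments):
        """Omitting each of the 8 instruments keeps the OR within [1.1345, 1.1505]."""
        results = leave_one_out(table1_instruments, model="fixed")
        ors = [r.pooled.or_ for r in results]
        assert min(ors) == pytest.approx(1.1345, abs=5e-5)
        assert max(ors) == pytest.approx(1.1505, abs=5e-5)
        assert all(o > 1 for o in ors)

    def test_exchangeable_instruments_give_zero_fluctuation(self):
        instruments = [make_instrument(variant_id=f"rs{i}") for i in range(4)]
        for res in leave_one_out(instruments, model="fixed"):
            assert res.fluctuation == pytest.approx(0.0, abs=1e-14)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            leave_one_out([make_instrument(), make_instrument(variant_id="rs2")])


class TestEgger:
    def test_exact_linear_data_recovered(self):
        instruments = [
            make_instrument(variant_id=f"rs{i}", beta_exposure=bx,
                            beta_outcome=0.01 + 0.2 * bx, se_outcome=0.01)
            for i, bx in enumerate([0.05, 0.08, 0.11, 0.14])
        ]
        res = egger_regression(instruments)
        assert res.intercept == pytest.approx(0.01, rel=1e-10)
        assert res.slope == pytest.approx(0.2, rel=1e-10)
        assert res.overdispersion == 1.0  # perfect fit floors at 1
        assert res.intercept_ci_low < res.intercept < res.intercept_ci_high
        assert res.slope_ci_low < res.slope < res.slope_ci_high

    def test_flat_response_gives_zero_slope(self):
        instruments = [
            make_instrument(variant_id=f"rs{i}", beta_exposure=bx,
                            beta_outcome=0.00995, se_outcome=0.0102)
            for i, bx in enumerate([0.06, 0.08, 0.1])
        ]
        res = egger_regression(instruments)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.00995, rel=1e-10)

    def test_degenerate_design_rejected(self):
        instruments = [make_instrument(variant_id=f"rs{i}", beta_exposure=0.1)
                       for i in range(3)]
        with pytest.raises(ValueError, match="singular"):
            egger_regression(instruments)
        with pytest.raises(ValueError):
            egger_regression(instruments[:2])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 12))
    def test_matches_closed_form_normal_equations(self, seed, k):
        rng = np.random.default_rng(seed)
        instruments = orient_exposure_positive(random_instruments(rng, k))
        x = np.array([i.beta_exposure for i in instruments])
        if np.ptp(x) == 0:
            return
        y = np.array([i.beta_outcome for i in instruments])
        w = np.array([i.se_outcome**-2 for i in instruments])
        a0, b0, sea0, seb0 = wls_normal_equations(x, y, w)
        res = egger_regression(instruments)
        assert res.intercept == pytest.approx(a0, rel=1e-10, abs=1e-14)
        assert res.slope == pytest.approx(b0, rel=1e-10, abs=1e-14)
        assert res.intercept_se == pytest.approx(sea0, rel=1e-9, abs=1e-14)
        assert res.slope_se == pytest.approx(seb0, rel=1e-9, abs=1e-14)
        assert res.overdispersion >= 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        instruments = random_instruments(rng, 8)
        shuffled = list(instruments)
        rng.shuffle(shuffled)
        a, b = egger_regression(instruments), egger_regression(shuffled)
        assert a.slope == pytest.approx(b.slope, rel=1e-10)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-10)

    def test_noise_free_valid_instruments_recover_ivw_slope(self):
        theta = 0.25
        instruments = [
            make_instrument(variant_id=f"rs{i}", beta_exposure=bx,
                            beta_outcome=theta * bx, se_outcome=0.01)
            for i, bx in enumerate([0.05, 0.07, 0.09, 0.12])
        ]
        res = egger_regression(instruments)
        ivw = ivw_pool([wald_ratio(i) for i in instruments], model="fixed")
        assert res.slope == pytest.approx(theta, rel=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert ivw.beta == pytest.approx(theta, rel=1e-12)

    def test_t_reference_widens_intervals(self):
        rng = np.random.default_rng(7)
        instruments = random_instruments(rng, 5)
        normal = egger_regression(instruments, p_method="normal")
        tdist = egger_regression(instruments, p_method="t")
        assert (tdist.slope_ci_high - tdist.slope_ci_low) > (
            normal.slope_ci_high - normal.slope_ci_low
        )
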