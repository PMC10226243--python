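"""Kaplan-Meier, step-function RMST and the smoothed hazard."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from survlock import (
    KMCurve,
    SurvivalDataset,
    km_conditional_rmst,
    km_fit,
    km_rmst,
    smoothed_hazard,
)


def naive_km(time, status, at):
    """Double-loop product-limit estimate at one time point."""
    s = 1.0
    for et in sorted(set(time[status == 1])):
        if et > at:
            break
        d = sum((time == et) & (status == 1))
        n = sum(time >= et)
        s *= 1.0 - d / n
    return s


def naive_step_rmst(time, status, horizon):
    """Rectangle sum under the naive product-limit curve."""
    knots = sorted({0.0, horizon} | {t for t, s in zip(time, status) if s == 1 and t < horizon})
    area = 0.0
    for a, b in zip(knots, knots[1:]):
        area += naive_km(time, status, a) * (b - a)
    return area


@st.composite
def small_datasets(draw):
    n = draw(st.integers(2, 30))
    times = draw(
        st.lists(st.floats(0.05, 20.0), min_size=n, max_size=n).map(np.array)
    )
    status = np.array(draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    if status.sum() == 0:
        status[0] = 1
    return SurvivalDataset(np.round(times, 2) + 0.01, status)


class TestKMFit:
    def test_hand_product_limit(self, hand_ds):
        curve = km_fit(hand_ds)
        np.testing.assert_allclose(curve.event_times, [1.0, 3.0])
        np.testing.assert_allclose(curve.surv, [2.0 / 3.0, 0.0])
        np.testing.assert_array_equal(curve.n_risk, [3, 1])
        np.testing.assert_array_equal(curve.n_event, [1, 1])
        assert curve.survival_at(0.5) == 1.0
        assert curve.survival_at(2.0) == pytest.approx(2.0 / 3.0)

    def test_all_censored_curve_stays_at_one(self):
        ds = SurvivalDataset(np.array([1.0, 2.0, 5.0]), np.zeros(3, dtype=int))
        curve = km_fit(ds)
        assert curve.event_times.size == 0
        assert curve.survival_at(4.9) == 1.0
        assert curve.last_obs == 5.0

    def test_ties_events_processed_before_censorings(self):
        ds = SurvivalDataset(np.array([2.0, 2.0, 2.0]), np.array([1, 0, 0]))
        curve = km_fit(ds)
        # the censored subjects are still at risk at the tied death time
        assert curve.n_risk[0] == 3
        assert curve.surv[0] == pytest.approx(2.0 / 3.0)

    def test_agrees_with_lifelines_pointwise(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(0)
        t = rng.exponential(4.0, 200)
        time = np.minimum(t, 6.0)
        status = (t <= 6.0).astype(int)
        curve = km_fit(SurvivalDataset(time, status))
        kmf = lifelines.KaplanMeierFitter().fit(time, status)
        ours = curve.survival_at(curve.event_times)
        theirs = kmf.predict(curve.event_times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    @given(small_datasets())
    def test_matches_naive_double_loop(self, ds):
        curve = km_fit(ds)
        if curve.event_times.size:
            last = curve.event_times[-1]
            assert curve.survival_at(last) == pytest.approx(
                naive_km(ds.time, ds.status, last), abs=1e-12
            )

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError, match="empty"):
            km_fit(SurvivalDataset(np.array([]), np.array([])))


class TestKMRMST:
    def test_no_events_rmst_equals_horizon(self):
        ds = SurvivalDataset(np.array([10.0, 12.0]), np.zeros(2, dtype=int))
        assert km_rmst(km_fit(ds), 8.0) == pytest.approx(8.0)

    def test_hand_rectangle_sum(self, hand_ds):
        # 1 * 1 + (2/3) * 2 over [0, 3]
        assert km_rmst(km_fit(hand_ds), 3.0) == pytest.approx(1 + 2 * 2.0 / 3.0)

    def test_halving_survival_halves_rmst(self, hand_ds):
        curve = km_fit(hand_ds)
        halved = KMCurve(
            event_times=curve.event_times,
            surv=curve.surv / 2.0,
            n_risk=curve.n_risk,
            n_event=curve.n_event,
            last_obs=curve.last_obs,
            greenwood_var=curve.greenwood_var,
        )
        # halving every post-event level halves each rectangle after the
        # first event; the leading strip keeps height 1 by construction
        assert km_rmst(halved, 3.0) == pytest.approx(1.0 * 1 + (1.0 / 3.0) * 2)

    def test_refuses_beyond_last_observation(self, hand_ds):
        curve = km_fit(hand_ds)
        with pytest.raises(ValueError, match="exceeds last observed"):
            km_rmst(curve, 10.0)
        with pytest.warns(UserWarning, match="extended flat"):
            val = km_rmst(curve, 10.0, extend_flat=True)
        assert val == pytest.approx(1 + 2 * 2.0 / 3.0)  # S is 0 beyond 3

    @given(small_datasets())
    def test_matches_naive_rectangle_sum(self, ds):
        curve = km_fit(ds)
        h = float(ds.time.max())
        assert km_rmst(curve, h) == pytest.approx(
            naive_step_rmst(ds.time, ds.status, h), abs=1e-10
        )


class TestConditionalRMST:
    def test_flat_curve(self):
        ds = SurvivalDataset(np.array([10.0, 12.0]), np.zeros(2, dtype=int))
        assert km_conditional_rmst(km_fit(ds), 3.0, 8.0) == pytest.approx(5.0)

    def test_hand_value(self, hand_ds):
        # integral of S on [1,3] is (2/3)*2; S(1) = 2/3
        assert km_conditional_rmst(km_fit(hand_ds), 1.0, 3.0) == pytest.approx(2.0)

    def test_zero_survival_at_t0_raises(self):
        # a km_fit curve can only hit zero at its very last observation, so
        # build the degenerate curve by hand
        curve = KMCurve(
            event_times=np.array([1.0, 2.0]),
            surv=np.array([0.5, 0.0]),
            n_risk=np.array([4, 2]),
            n_event=np.array([2, 2]),
            last_obs=5.0,
            greenwood_var=np.zeros(2),
        )
        with pytest.raises(ValueError, match="undefined"):
            km_conditional_rmst(curve, 3.0, 5.0)

    @given(small_datasets(), st.floats(0.1, 0.9), st.floats(0.2, 0.95))
    def test_additivity_identity(self, ds, f0, f1):
        curve = km_fit(ds)
        h = float(ds.time.max())
        t0 = f0 * min(f1, 0.99) * h
        if t0 <= 0 or t0 >= h or curve.survival_at(t0) <= 0:
            return
        lhs = km_conditional_rmst(curve, t0, h) * curve.survival_at(t0) + km_rmst(curve, t0)
        assert lhs == pytest.approx(km_rmst(curve, h), abs=1e-9)


class TestSmoothedHazard:
    def test_recovers_constant_hazard(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1 / 0.3, 5000)
        time = np.minimum(t, 12.0)
        status = (t <= 12.0).astype(int)
        hz = smoothed_hazard(SurvivalDataset(time, status))
        lo, hi = np.quantile(hz.grid, [0.25, 0.75])
        sel = (hz.grid >= lo) & (hz.grid <= hi)
        assert np.all(np.abs(hz.hazard[sel] - 0.3) < 0.2 * 0.3)

    def test_nonnegative_everywhere(self, piecewise_locked):
        hz = smoothed_hazard(piecewise_locked)
        assert np.all(hz.hazard >= 0)

    def test_doubling_bandwidth_does_not_raise_total_variation(self, hand_ds):
        ds = SurvivalDataset(
            np.array([0.5, 1.0, 1.4, 2.0, 2.6, 3.1, 4.0, 5.5]),
            np.array([1, 1, 0, 1, 1, 0, 1, 1]),
        )
        tv = {}
        for b in [0.5, 1.0, 2.0]:
            hz = smoothed_hazard(ds, bandwidth=b)
            tv[b] = np.abs(np.diff(hz.hazard)).sum()
        assert tv[1.0] <= tv[0.5] + 1e-12
        assert tv[2.0] <= tv[1.0] + 1e-12

    def test_needs_two_events(self):
        ds = SurvivalDataset(np.array([1.0, 2.0]), np.array([1, 0]))
        with pytest.raises(ValueError, match="2 events"):
            smoothed_hazard(ds)
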