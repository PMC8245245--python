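import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mupool as mp
from mupool.force import _s


def naive_unit_force(spikes, twitch, t_grid):
    """Term-by-term superposition of gain-scaled twitches (reference oracle)."""
    gains = mp.discharge_gains(spikes, twitch.T)
    out = np.zeros_like(t_grid)
    for t0, g in zip(spikes, gains):
        u = np.clip(t_grid - t0, 0.0, None) / twitch.T
        out += g * twitch.P * u * np.exp(1.0 - u)
    return out


class TestTwitchParameters:
    @pytest.mark.parametrize(
        "i, rp, n, expected",
        [(120, 100.0, 120, 100.0), (60, 100.0, 120, 10.0), (5, 1.0, 120, 1.0)],
    )
    def test_peak_twitch(self, i, rp, n, expected):
        assert mp.peak_twitch(i, rp, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "p, expected",
        [(1.0, 90.0), (100.0, 30.0), (10.0, 90.0 * 0.1 ** (math.log(3) / math.log(100)))],
    )
    def test_contraction_time(self, p, expected):
        assert mp.contraction_time(p, 90.0, 3.0, 100.0) == pytest.approx(expected, rel=1e-12)

    def test_contraction_time_decreasing_in_p(self):
        t = [mp.contraction_time(p, 90, 3, 100) for p in (1, 3, 10, 30, 100)]
        assert np.all(np.diff(t) < 0)

    def test_fold_range_conservation(self, default_pool):
        """Realized P spread is RP**((n-1)/n) — the closed form, not the rounded prose."""
        p = np.array([u.peak_twitch for u in default_pool])
        t = np.array([u.contraction_time_ms for u in default_pool])
        assert p.max() / p.min() == pytest.approx(100.0 ** (119 / 120), rel=1e-9)
        assert t.max() / t.min() == pytest.approx(3.0 ** (119 / 120), rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(IndexError):
            mp.peak_twitch(0, 100, 120)
        with pytest.raises(ValueError):
            mp.peak_twitch(1, 0.0, 120)
        with pytest.raises(ValueError):
            mp.contraction_time(-1.0, 90, 3, 100)


class TestTwitchResponse:
    def test_peak_at_contraction_time(self):
        assert mp.twitch_response(0.05, 1.0, 7.0, 0.05) == pytest.approx(7.0)

    def test_zero_at_onset(self):
        assert mp.twitch_response(0.0, 1.0, 7.0, 0.05) == 0.0

    def test_closed_form_point(self):
        # t = 2T: (2)e^{-1} of the peak
        assert mp.twitch_response(0.2, 1.0, 100.0, 0.1) == pytest.approx(200 * math.exp(-1))

    @given(st.floats(min_value=1e-3, max_value=10.0))
    def test_peak_never_exceeded(self, t):
        assert mp.twitch_response(t, 1.0, 5.0, 0.7) <= 5.0 + 1e-12


class TestFusionGain:
    def test_unfused_regime(self):
        assert mp.fusion_gain(0.02, 0.1) == 1.0  # T/ISI = 0.2

    def test_continuity_at_knee(self):
        assert mp.fusion_gain(0.04, 0.1) == pytest.approx(1.0, rel=1e-12)
        assert mp.fusion_gain(0.0400001, 0.1) == pytest.approx(1.0, rel=1e-4)

    def test_value_at_matched_interval(self):
        expected = (1 - math.exp(-2)) / ((1 - math.exp(-0.128)) / 0.4)
        assert mp.fusion_gain(0.1, 0.1) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.879, abs=5e-4)

    def test_peak_near_matched_interval(self):
        x = np.linspace(0.5, 3.0, 20001)
        assert 0.95 <= x[np.argmax(_s(x))] <= 1.10

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mp.fusion_gain(0.0, 0.1)
        with pytest.raises(ValueError):
            mp.fusion_gain(0.1, 0.0)

    def test_first_discharge_gain_is_one(self):
        gains = mp.discharge_gains(np.array([0.0, 0.05, 0.1]), 0.09)
        assert gains[0] == 1.0
        assert np.all(gains[1:] > 1.0)


class TestUnitForce:
    def test_matches_term_by_term_oracle(self, rng):
        t_grid = np.arange(0, 2.0, 0.001)
        for _ in range(5):
            spikes = np.sort(rng.uniform(0, 1.0, rng.integers(1, 6)))
            tw = mp.TwitchParams(P=rng.uniform(1, 100), T=rng.uniform(0.03, 0.09))
            fast = mp.unit_force(spikes, tw, t_grid)
            ref = naive_unit_force(spikes, tw, t_grid)
            assert np.max(np.abs(fast - ref)) <= 1e-9 * ref.max()

    def test_single_spike_is_one_twitch(self):
        tw = mp.TwitchParams(P=10.0, T=0.05)
        t_grid = np.arange(0, 1.0, 0.001)
        f = mp.unit_force(np.array([0.1]), tw, t_grid)
        assert f[:100].max() == 0.0
        assert f.max() == pytest.approx(10.0, rel=1e-6)  # peak P at t0 + T
        assert abs(t_grid[np.argmax(f)] - 0.15) <= 1e-9

    def test_widely_spaced_spikes_keep_unit_gain(self):
        tw = mp.TwitchParams(P=10.0, T=0.03)
        t_grid = np.arange(0, 3.0, 0.001)
        f = mp.unit_force(np.array([0.2, 1.6]), tw, t_grid)  # ISI >> T/0.4
        first = f[(t_grid >= 0.2) & (t_grid < 1.0)].max()
        second = f[t_grid >= 1.6].max()
        assert second == pytest.approx(first, rel=1e-4)

    def test_fused_train_exceeds_twice_single_twitch(self):
        tw = mp.TwitchParams(P=10.0, T=0.05)
        t_grid = np.arange(0, 3.0, 0.001)
        spikes = np.arange(0.1, 2.5, tw.T)  # ISI = T: near-maximal fusion gain
        f = mp.unit_force(spikes, tw, t_grid)
        assert f[(t_grid > 1.5) & (t_grid < 2.4)].min() > 2 * tw.P

    def test_rate_saturation_plateau(self):
        """Mean steady force is flat (within 1%) between rates 2/T and 3/T."""
        tw = mp.TwitchParams(P=10.0, T=0.05)
        t_grid = np.arange(0, 10.0, 0.001)
        means = []
        for rate in (2 / tw.T, 3 / tw.T):
            spikes = np.arange(0.0, 10.0, 1 / rate)
            f = mp.unit_force(spikes, tw, t_grid)
            means.append(f[t_grid >= 2.0].mean())
        assert means[1] == pytest.approx(means[0], rel=0.01)

    def test_unordered_spikes_rejected(self):
        with pytest.raises(ValueError):
            mp.unit_force(np.array([0.5, 0.1]), mp.TwitchParams(1, 0.05), np.arange(0, 1, 0.001))


class TestTotalForce:
    def test_linearity(self, rng):
        a = rng.uniform(size=100)
        b = rng.uniform(size=100)
        assert np.allclose(mp.total_force([a, b]), a + b)
        assert np.allclose(mp.total_force([a, a]), 2 * a)

    def test_single_and_empty(self):
        a = np.ones(10)
        assert np.array_equal(mp.total_force([a]), a)
        with pytest.raises(ValueError):
            mp.total_force([])

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            mp.total_force([np.ones(10), np.ones(11)])
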