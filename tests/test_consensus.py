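import itertools

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from coopaffect import (ConsensusConfig, Trace, consensus_predict,
                        extrapolate, optimal_window, split_by_threshold,
                        sufficiency_check)
from coopaffect.consensus import NO_WINDOW


def tr(values, period=0.04, mask=None):
    return Trace(period, np.asarray(values, dtype=float), valid_mask=mask)


def brute_force_split(values):
    """Oracle: enumerate every bipartition-by-threshold of defined values."""
    v = np.asarray(values, dtype=float)
    idx = np.flatnonzero(~np.isnan(v))
    vals = v[idx]
    best = None
    for thr in np.unique(vals)[:-1]:
        above = idx[vals > thr]
        below = idx[vals <= thr]
        obj = v[above].mean() - v[below].mean()
        if best is None or obj > best[0] + 1e-15:
            best = (obj, set(above.tolist()))
    if best is None:  # all equal
        return set(idx.tolist()), 0.0
    return best[1], best[0]


class TestSplit:
    @pytest.mark.parametrize("vals, retained, objective", [
        ([0.9, 0.85, 0.2], {0, 1}, 0.675),
        ([0.5, 0.5, 0.5], {0, 1, 2}, 0.0),
        ([0.9, -0.3], {0}, 1.2),
    ])
    def test_examples(self, vals, retained, objective):
        thr, ret, obj = split_by_threshold(vals)
        assert set(ret.tolist()) == retained
        assert obj == pytest.approx(objective)

    def test_nan_members_never_retained(self):
        thr, ret, _ = split_by_threshold([0.8, np.nan, 0.1, 0.75])
        assert set(ret.tolist()) == {0, 3}

    def test_too_few_defined_entries_rejected(self):
        with pytest.raises(ValueError):
            split_by_threshold([0.5, np.nan])

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            vals = np.round(rng.uniform(-1, 1, n), 3)
            if rng.random() < 0.3:
                vals[rng.integers(0, n)] = np.nan
            if np.sum(~np.isnan(vals)) < 2:
                continue
            _, ret, obj = split_by_threshold(vals)
            oracle_ret, oracle_obj = brute_force_split(vals)
            assert set(ret.tolist()) == oracle_ret
            assert obj == pytest.approx(oracle_obj)


class TestOptimalWindow:
    def test_identical_traces_take_smallest_width(self):
        base = np.sin(np.arange(300) * 0.1)
        cfg = ConsensusConfig(window_widths=(1.0, 2.0, 3.0))
        width, retained, avg = optimal_window([tr(base)] * 3, t_end=8.0,
                                              config=cfg)
        assert width == 1.0 and avg == pytest.approx(1.0)
        assert set(retained.tolist()) == {0, 1, 2}

    def test_widths_not_fitting_history_skipped(self):
        base = np.sin(np.arange(300) * 0.1)
        cfg = ConsensusConfig(window_widths=(1.0, 2.0, 4.0))
        # at t=1.2 s only the 1 s window has its full sample complement
        width, _, _ = optimal_window([tr(base), tr(base + 0.1)], 1.2, cfg)
        assert width == 1.0

    def test_returns_sentinel_when_every_width_fails(self):
        # constant traces: every pairwise CCC defined but all averages equal;
        # masked-out members make all splits undefined
        a = tr(np.full(100, np.nan), mask=np.zeros(100, bool))
        cfg = ConsensusConfig(window_widths=(1.0,))
        assert optimal_window([a, a], 3.0, cfg) is NO_WINDOW

    def test_small_ensemble_rejected(self):
        cfg = ConsensusConfig()
        with pytest.raises(ValueError):
            optimal_window([tr(np.arange(100.0))], 2.0, cfg)


class TestExtrapolate:
    def test_constant_traces_extrapolate_to_constant(self):
        out = extrapolate([tr(np.full(100, 0.4))] * 3, t_n=2.0,
                          fit_interval=1.0)
        assert out == pytest.approx(0.4)

    def test_pooled_parallel_lines_average(self):
        t = np.arange(100) * 0.04
        out = extrapolate([tr(t), tr(t + 0.2)], t_n=t[50], fit_interval=1.0)
        assert out == pytest.approx(t[51] + 0.1)

    def test_single_linear_trace_exact(self):
        t = np.arange(100) * 0.04
        out = extrapolate([tr(3.0 * t - 1.0)], t_n=t[80], fit_interval=1.0)
        assert out == pytest.approx(3.0 * t[81] - 1.0)

    def test_empty_retained_rejected(self):
        with pytest.raises(ValueError):
            extrapolate([], 1.0, 1.0)


class TestConsensusPredict:
    @pytest.fixture()
    def smooth_ensemble(self, rng):
        T = 400
        return [tr(gaussian_filter1d(rng.standard_normal(T), 15))
                for _ in range(4)]

    def test_unanimous_ensemble_reproduces_member(self):
        # a linear member makes the one-frame extrapolation exact, so the
        # unanimity property can be asserted to machine precision
        base = 0.5 * np.arange(500) * 0.04 - 2.0
        cfg = ConsensusConfig(window_widths=(1.0, 2.0))
        label, diags = consensus_predict([tr(base)] * 3, cfg)
        first = int(round(1.0 / 0.04))
        assert np.flatnonzero(label.valid_mask)[0] == first
        v = label.valid_mask
        assert np.allclose(label.values[v], base[v], atol=1e-9)
        # smallest width wins the tie among unanimous members
        assert diags.width[first] == 1.0

    def test_matches_scalar_chain(self, smooth_ensemble):
        cfg = ConsensusConfig(window_widths=(1.0, 2.0, 3.0))
        label, diags = consensus_predict(smooth_ensemble, cfg)
        t = smooth_ensemble[0].times
        for i in range(30, 399, 23):
            res = optimal_window(smooth_ensemble, t[i], cfg)
            if res is NO_WINDOW:
                assert not label.valid_mask[i + 1]
                continue
            width, retained, avg = res
            if avg < 0:
                assert not label.valid_mask[i + 1]
                continue
            assert width == diags.width[i]
            assert set(retained.tolist()) == set(
                np.flatnonzero(diags.retained[:, i]).tolist())
            val = extrapolate([smooth_ensemble[j] for j in retained], t[i],
                              cfg.fit_interval)
            assert label.values[i + 1] == pytest.approx(val, abs=1e-9)

    def test_anticorrelated_ensemble_yields_missing_output(self):
        # three sines 120 degrees apart are pairwise anti-correlated
        # (rho = -0.5), so the optimal concordance is negative everywhere
        t = np.arange(600) * 0.04
        phase = 2 * np.pi / 3
        ens = [tr(np.sin(2 * np.pi * t / 4.0 + k * phase)) for k in range(3)]
        label, _ = consensus_predict(ens, ConsensusConfig(
            window_widths=(2.0, 4.0), fit_interval=1.0))
        assert label.valid_fraction < 0.05

    def test_duplicating_retained_members_is_noop_for_pooled_fit(
            self, smooth_ensemble):
        # Duplicating a single member double-weights its samples in the
        # pooled fit and can shift the retained set (known behavior of
        # pooled fitting, documented); duplicating *every* member leaves
        # the pooled least-squares fit — and the output — unchanged
        # wherever the retained composition is preserved.
        cfg = ConsensusConfig(window_widths=(1.0, 2.0))
        base_label, d1 = consensus_predict(smooth_ensemble, cfg)
        doubled = smooth_ensemble + [m.copy() for m in smooth_ensemble]
        label2, d2 = consensus_predict(doubled, cfg)
        both = base_label.valid_mask & label2.valid_mask
        idx = np.flatnonzero(both)
        same_comp = np.array([
            np.array_equal(d1.retained[:, i - 1], d2.retained[:4, i - 1])
            and np.array_equal(d1.retained[:, i - 1], d2.retained[4:, i - 1])
            for i in idx])
        idx = idx[same_comp]
        assert idx.size > 50
        assert np.allclose(base_label.values[idx], label2.values[idx],
                           atol=1e-9)

    def test_order_invariance(self, smooth_ensemble):
        cfg = ConsensusConfig(window_widths=(1.0, 2.0))
        l1, _ = consensus_predict(smooth_ensemble, cfg)
        l2, _ = consensus_predict(smooth_ensemble[::-1], cfg)
        assert np.array_equal(l1.valid_mask, l2.valid_mask)
        assert np.allclose(l1.values[l1.valid_mask],
                           l2.values[l2.valid_mask], atol=1e-9)

    def test_output_within_extended_member_range(self, smooth_ensemble):
        cfg = ConsensusConfig(window_widths=(1.0, 2.0))
        label, diags = consensus_predict(smooth_ensemble, cfg)
        V = np.vstack([m.values for m in smooth_ensemble])
        dt = 0.04
        fw = int(round(cfg.fit_interval / dt))
        for i in np.flatnonzero(label.valid_mask)[::17]:
            ret = np.flatnonzero(diags.retained[:, i - 1])
            window = V[ret, max(0, i - fw): i]
            # linear fit over the interval cannot leave the sample range by
            # more than one slope step
            span = window.max() - window.min() + 1e-12
            slope_step = span / max(1, fw - 1)
            assert window.min() - 2 * slope_step <= label.values[i] \
                <= window.max() + 2 * slope_step


class TestSufficiency:
    def test_boundary_is_inclusive(self):
        cfg = ConsensusConfig(sufficiency_fraction=0.5)
        half = tr(np.arange(10.0), mask=[1] * 5 + [0] * 5)
        assert sufficiency_check(half, cfg)
        assert sufficiency_check(tr(np.arange(10.0)), cfg)
        empty = tr(np.full(10, np.nan), mask=np.zeros(10, bool))
        assert not sufficiency_check(empty, cfg)


class TestConfigValidation:
    def test_fit_interval_must_fit_smallest_width(self):
        with pytest.raises(ValueError):
            ConsensusConfig(window_widths=(2.0, 4.0), fit_interval=3.0)

    def test_widths_must_be_sorted(self):
        with pytest.raises(ValueError):
            ConsensusConfig(window_widths=(2.0, 1.0))
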