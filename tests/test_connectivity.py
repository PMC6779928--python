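"""Hilbert phase, PLI estimation, window averaging, edge statistics."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

from srmeeg.connectivity import (EDGE_TRIM_MS, PhaseTensor, PLIMatrix,
                                 analytic_phase, edge_significance,
                                 mean_strength, pli_timeseries, window_pli,
                                 wrap_phase)
from srmeeg.preprocess import bandpass

from conftest import make_epochs
from helpers import naive_pli

FS = 500.0


def _phase_tensor(phase, fs=FS, t0=-300.0, trim=True):
    phase = np.asarray(phase, dtype=float)
    valid = np.ones(phase.shape[1], dtype=bool)
    if trim:
        n = int(round(EDGE_TRIM_MS * fs / 1000.0))
        valid[:n] = False
        valid[-n:] = False
    return PhaseTensor(phase, valid, fs, t0)


def _alpha_epochs(data):
    return bandpass(make_epochs(data), 8.0, 13.0)


class TestAnalyticPhase:
    def test_tone_phase_slope_matches_frequency(self):
        t = (np.arange(550) / FS) - 0.3
        x = np.sin(2 * np.pi * 10.0 * t)
        es = make_epochs(np.repeat(x[None, :, None], 2, axis=2))
        ph = analytic_phase(es, check_band=False)
        un = np.unwrap(ph.phase[0, ph.valid, 0])
        slope = np.polyfit(np.arange(un.size) / FS, un, 1)[0]
        assert abs(slope - 2 * np.pi * 10.0) / (2 * np.pi * 10.0) < 0.01

    def test_edge_trim_is_100ms(self):
        es = _alpha_epochs(np.random.default_rng(0).standard_normal((1, 550, 2)))
        ph = analytic_phase(es)
        assert (~ph.valid[:50]).all() and (~ph.valid[-50:]).all()
        assert ph.valid[50:-50].all()

    def test_identical_channels_zero_phase_difference(self, rng):
        x = rng.standard_normal((1, 550, 3))
        es = _alpha_epochs(np.concatenate([x, x], axis=0))
        ph = analytic_phase(es)
        d = ph.phase[0] - ph.phase[1]
        assert np.allclose(d[ph.valid], 0.0)

    def test_quarter_cycle_delay_gives_half_pi(self):
        t = (np.arange(550) / FS) - 0.3
        a = np.sin(2 * np.pi * 10.0 * t)
        b = np.sin(2 * np.pi * 10.0 * (t - 0.025))  # 25 ms at 10 Hz
        es = make_epochs(np.stack([a, b])[:, :, None])
        ph = analytic_phase(es, check_band=False)
        d = wrap_phase(ph.phase[0, ph.valid, 0] - ph.phase[1, ph.valid, 0])
        assert np.allclose(d, np.pi / 2, atol=0.05)

    def test_broadband_input_warns(self, rng):
        es = make_epochs(rng.standard_normal((2, 550, 2)))
        with pytest.warns(UserWarning, match="narrow-band"):
            analytic_phase(es)


class TestPLITimeseries:
    def test_consistent_positive_lag_gives_one(self):
        ph = _phase_tensor(np.zeros((2, 550, 4)))
        ph.phase[0] += 0.4  # channel 0 leads in every trial
        s = pli_timeseries(ph)
        assert np.allclose(s.pli[0, ph.valid], 1.0)

    def test_sign_pattern_three_quarters(self):
        # signs (+, +, -, +) -> |(1 + 1 - 1 + 1)| / 4 = 0.5
        ph = _phase_tensor(np.zeros((2, 550, 4)))
        ph.phase[0, :, :] = [[0.3, 0.3, -0.3, 0.3]] * 550
        s = pli_timeseries(ph)
        assert np.allclose(s.pli[0, ph.valid], 0.5)

    def test_zero_lag_scaled_copy_gives_exact_zero(self, rng):
        x = rng.standard_normal((1, 550, 5))
        es = _alpha_epochs(np.concatenate([x, 0.5 * x], axis=0))
        s = pli_timeseries(analytic_phase(es))
        assert np.all(s.pli[0, s.valid] == 0.0)

    def test_vectorised_matches_naive_loop_bit_exactly(self, rng):
        for _ in range(25):
            C = rng.integers(2, 5)
            ph = rng.uniform(-np.pi, np.pi, (C, 6, 5))
            got = pli_timeseries(_phase_tensor(ph, trim=False)).pli
            assert np.array_equal(got, naive_pli(ph))

    @given(hnp.arrays(np.float64, (3, 8, 4),
                      elements=hst.floats(-np.pi, np.pi)))
    def test_bounds_property(self, ph):
        s = pli_timeseries(_phase_tensor(ph, trim=False))
        assert np.all(s.pli >= 0.0) and np.all(s.pli <= 1.0)

    @given(hnp.arrays(np.float64, (2, 6, 5),
                      elements=hst.floats(-np.pi, np.pi)))
    def test_channel_order_invariance(self, ph):
        a = pli_timeseries(_phase_tensor(ph, trim=False)).pli
        b = pli_timeseries(_phase_tensor(ph[::-1], trim=False)).pli
        assert np.array_equal(a, b)

    def test_needs_two_trials(self):
        with pytest.raises(ValueError, match="trials"):
            pli_timeseries(_phase_tensor(np.zeros((2, 550, 1))))


class TestWindowPLI:
    def test_constant_series_fills_matrix(self):
        ph = _phase_tensor(np.zeros((3, 550, 4)))
        ph.phase[0] += 0.4
        ph.phase[1] += 0.2
        m = window_pli(pli_timeseries(ph), (100.0, 300.0))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(m.m[off], 1.0)
        assert np.allclose(np.diag(m.m), 0.0)

    def test_three_sample_arithmetic_oracle(self):
        ph = _phase_tensor(np.zeros((2, 550, 4)))
        s = pli_timeseries(ph)
        s.pli[:] = 0.0
        sl = np.flatnonzero(s.valid & (np.arange(550) >= 200)
                            & (np.arange(550) < 203))
        s.valid[:] = False
        s.valid[sl] = True
        s.pli[0, sl] = [0.2, 0.4, 0.9]
        m = window_pli(s, (100.0, 300.0))
        assert m.m[0, 1] == pytest.approx((0.2 + 0.4 + 0.9) / 3)

    def test_window_inside_trimmed_edges_raises(self):
        ph = _phase_tensor(np.zeros((2, 550, 3)))
        s = pli_timeseries(ph)
        with pytest.raises(ValueError, match="valid"):
            window_pli(s, (-300.0, -250.0))

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            PLIMatrix(np.array([[0.0, 1.5], [1.5, 0.0]]), (0.0, 1.0))
        with pytest.raises(ValueError):
            PLIMatrix(np.array([[0.0, 0.2], [0.3, 0.0]]), (0.0, 1.0))


class TestMeanStrength:
    def test_uniform_matrix(self):
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 0.0)
        assert mean_strength(PLIMatrix(m, (0, 1))) == pytest.approx(0.3)

    def test_three_node_toy(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.2
        m[0, 2] = m[2, 0] = 0.4
        m[1, 2] = m[2, 1] = 0.6
        assert mean_strength(PLIMatrix(m, (0, 1))) == pytest.approx(0.4)


def _random_matrices(rng, n_subj, n=6, shift=0.0, edges=()):
    mats = []
    for _ in range(n_subj):
        w = rng.uniform(0.05, 0.3, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        for (i, j) in edges:
            w[i, j] = w[j, i] = min(1.0, w[i, j] + shift)
        mats.append(PLIMatrix(w, (100.0, 300.0)))
    return mats


class TestEdgeSignificance:
    def test_identical_sets_pass_nothing(self, rng):
        act = _random_matrices(rng, 6)
        res = edge_significance(act, act)
        assert res.mask.sum() == 0
        assert np.allclose(res.p_raw, 1.0)

    def test_planted_shift_detected(self):
        edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5),
                 (0, 3), (1, 4), (2, 5), (0, 5)]
        detected = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            base = _random_matrices(r, 18)
            act = _random_matrices(r, 18, shift=0.25, edges=edges)
            res = edge_significance(act, base)
            sig = {tuple(p) for p in res.pairs[res.mask]}
            detected += sum(e in sig for e in edges) >= 9
        assert detected >= 8

    def test_label_permutation_calibrates(self, rng):
        rates = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            pooled = _random_matrices(r, 24)
            perm = r.permutation(24)
            res = edge_significance([pooled[i] for i in perm[:12]],
                                    [pooled[i] for i in perm[12:]])
            rates.append((res.p_raw < 0.05).mean())
        assert 0.02 < np.mean(rates) < 0.09

    def test_paired_variant_runs(self, rng):
        act = _random_matrices(rng, 8)
        base = _random_matrices(rng, 8)
        res = edge_significance(act, base, paired=True)
        assert res.p_raw.shape == res.t.shape

    def test_subject_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            edge_significance(_random_matrices(rng, 4),
                              _random_matrices(rng, 5))


class TestVolumeConductionImmunity:
    def test_common_source_mixture_yields_zero_pli(self):
        from srmeeg.synth import SimulationConfig, gen_epoch_set
        amps = {"control": {c: 0.0 for c in ("self", "other", "physical")},
                "patient": {c: 0.0 for c in ("self", "other", "physical")}}
        cfg = SimulationConfig(
            n_per_group=1, n_channels=2, fs=250.0, burst_amp=amps,
            coupling_amp=0.0, noise_rms=0.0, alpha_amp_cv=0.0,
            common_source_edges=[(0, 1)], common_source_amp=5.0, seed=2)
        es = gen_epoch_set(cfg, "control-00", "control", "self", seed=9)
        ph = analytic_phase(bandpass(es, 8.0, 13.0), check_band=False)
        s = pli_timeseries(ph)
        m = window_pli(s, (100.0, 300.0))
        assert m.m[0, 1] == 0.0
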