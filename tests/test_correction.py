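import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import as4dpm as m


def _breathing(seed=5, n=302, amplitude=10.0):
    params = m.BreathingParams(seed=seed, noise_sd=0.0)
    return m.simulate_breathing(params, n, amplitude=amplitude).waveform.values


class TestPhaseInversion:
    def test_inverted_and_aligned_signals(self):
        x = np.sin(np.linspace(0, 20, 200))
        assert m.detect_phase_inversion(x, -x) == -1
        assert m.detect_phase_inversion(x, x) == 1

    def test_simulated_negative_lr_correlation(self, clean_case):
        wav = m.shroud_waveform(clean_case.projections)
        target = clean_case.true_target
        assert m.detect_phase_inversion(wav, target.component("LR")) == -1
        assert m.detect_phase_inversion(wav, target.component("SI")) == 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            m.detect_phase_inversion(np.zeros(10), np.arange(10.0))


class TestGlobalMatch:
    def test_full_range_endpoints_scale_directly(self):
        w_as = np.array([0.0, 0.25, 0.5, 1.0])
        w_4d = np.array([0.0, 10.0, 3.0, 7.0])
        params = m.MatchingParams(p_upper=100, p_lower=0, window=11)
        out = m.global_match(w_as, w_4d, params)
        assert np.allclose(out, 10.0 * w_as)

    def test_identity_when_signals_match(self):
        x = _breathing()
        params = m.MatchingParams(p_upper=100, p_lower=0, window=11)
        assert np.allclose(m.global_match(x, x, params), x)

    def test_hand_computed_percentile_mapping(self):
        # source with P85 = 8 and P10 = 2 exactly (21-point linear grid)
        source = np.linspace(1.2, 9.2, 21)
        assert np.percentile(source, 85) == pytest.approx(8.0)
        assert np.percentile(source, 10) == pytest.approx(2.0)
        w_4d = np.array([0.0, 10.0, 5.0])
        params = m.MatchingParams(p_upper=85, p_lower=10)
        out = m.global_match(
            np.array([5.0, 2.0, 8.0]), w_4d, params, percentile_source=source
        )
        assert np.allclose(out, [5.0, 0.0, 10.0])

    def test_percentile_endpoints_map_onto_target_range(self):
        rng = np.random.default_rng(0)
        w_as = rng.normal(size=400)
        w_4d = rng.uniform(-3, 9, 400)
        for hi, lo in m.PERCENTILE_CANDIDATES:
            params = m.MatchingParams(p_upper=hi, p_lower=lo)
            p_hi, p_lo = np.percentile(w_as, [hi, lo])
            out = m.global_match(np.array([p_lo, p_hi]), w_4d, params,
                                 percentile_source=w_as)
            assert out[0] == pytest.approx(w_4d.min())
            assert out[1] == pytest.approx(w_4d.max())

    def test_degenerate_span_rejected(self):
        params = m.MatchingParams(p_upper=85, p_lower=10)
        with pytest.raises(ValueError, match="degenerate"):
            m.global_match(np.ones(10), np.arange(10.0), params,
                           percentile_source=np.ones(10))

    @settings(derandomize=True, max_examples=50)
    @given(
        hnp.arrays(
            float,
            st.integers(10, 60),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    def test_affine_map_preserves_ordering(self, w_as):
        w_4d = np.linspace(-2.0, 5.0, len(w_as))
        params = m.MatchingParams(p_upper=85, p_lower=10)
        try:
            out = m.global_match(w_as, w_4d, params)
        except ValueError:
            return  # degenerate percentile span
        order = np.argsort(w_as, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-9)


class TestLocalMatch:
    def test_identity_when_signals_agree(self):
        x = _breathing()
        assert np.allclose(m.local_match(x, x, 21), x)

    def test_exact_for_global_affine_discrepancy(self):
        x = _breathing()
        assert np.allclose(m.local_match(x, 2.0 * x + 3.0, 21), 2.0 * x + 3.0)

    def test_single_window_matches_min_and_max(self):
        x = _breathing(n=51)
        y = _breathing(seed=9, n=51) * 1.7 + 0.4
        w = 51
        out = m.local_match(x, y, w)
        assert out.min() == pytest.approx(y.min())
        assert out.max() == pytest.approx(y.max())

    def test_flat_target_window_shifts_to_mean(self):
        x = np.zeros(11)
        y = np.linspace(1.0, 2.0, 11)
        out = m.local_match(x, y, 11)
        assert np.allclose(out, y.mean())

    def test_even_or_tiny_window_rejected(self):
        x = np.arange(30.0)
        with pytest.raises(ValueError):
            m.local_match(x, x, 10)
        with pytest.raises(ValueError):
            m.local_match(x, x, 1)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 1000))
    def test_output_bounded_by_covering_windows(self, seed):
        rng = np.random.default_rng(seed)
        n, w = 60, 11
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        out = m.local_match(x, y, w)
        n_win = n - w + 1
        for t in range(n):
            los = range(max(0, t - w + 1), min(t, n_win - 1) + 1)
            bounds = [(y[s : s + w].min(), y[s : s + w].max()) for s in los]
            lo = min(b[0] for b in bounds)
            hi = max(b[1] for b in bounds)
            assert lo - 1e-9 <= out[t] <= hi + 1e-9


class TestCorrectWaveform:
    def _setup(self, shrink):
        trace = _breathing(seed=3, n=302, amplitude=11.4)
        truth = m.Waveform(np.column_stack([-0.15 * trace, trace, -0.3 * trace]))
        mean = truth.values.mean(axis=0)
        w4d = m.Waveform(mean + shrink * (truth.values - mean))
        w_as = 0.8 * trace + 5.0  # faithful surrogate, arbitrary units
        return truth, w4d, w_as

    def test_correction_recovers_underestimated_amplitude(self):
        truth, w4d, w_as = self._setup(shrink=0.7)
        corrected = m.correct_waveform(w4d, w_as)
        rmse = lambda a, b: np.sqrt(np.mean((a - b) ** 2))
        for d in range(3):
            before = rmse(w4d.values[:, d], truth.values[:, d])
            after = rmse(corrected.waveform.values[:, d], truth.values[:, d])
            assert after < before

    def test_near_identity_when_target_is_exact(self):
        # full-range percentiles: (P85, P10) would deliberately stretch
        truth, w4d, w_as = self._setup(shrink=1.0)
        params = m.MatchingParams(p_upper=100, p_lower=0, window=21)
        corrected = m.correct_waveform(w4d, w_as, params)
        for d in range(3):
            amp = np.ptp(truth.values[:, d])
            rmse = np.sqrt(
                np.mean((corrected.waveform.values[:, d] - truth.values[:, d]) ** 2)
            )
            assert rmse < 0.05 * amp

    def test_signs_follow_correlation_structure(self):
        truth, w4d, w_as = self._setup(shrink=0.7)
        corrected = m.correct_waveform(w4d, w_as)
        assert corrected.signs.tolist() == [-1, 1, -1]

    def test_output_lengths_match_input(self):
        truth, w4d, w_as = self._setup(shrink=0.7)
        corrected = m.correct_waveform(w4d, w_as)
        assert corrected.waveform.n_frames == w4d.n_frames
        assert corrected.w_as_prime.shape == w4d.values.shape
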