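import numpy as np
import pytest

import as4dpm as m
from as4dpm.shroud import _centroid_reference
from as4dpm.simulate import ProjectionStack, render_projection


def _stack_from_edges(edge_rows, shape=(256, 32), noise_sd=0.0, seed=0, hw=2.0):
    rng = np.random.default_rng(seed)
    pp = m.ProjectionParams(
        image_shape=shape,
        noise_sd=noise_sd,
        dome_sag_px=0.0,
        texture_amplitude=0.0,
        edge_halfwidth_px=hw,
    )
    frames = np.stack(
        [render_projection(float(e), params=pp, rng=rng) for e in edge_rows]
    )
    n = len(edge_rows)
    return ProjectionStack(
        frames=frames,
        times=0.2 * np.arange(n),
        angles=0.3 * np.arange(n),
        pixel_size_mm=0.2,
        imager=m.ImagerGeometry(1, 0.0),
    )


def _ridge_image(center_rows, n_rows=120, noise_sd=0.0, seed=0):
    """Synthetic shroud image: a breathing ridge plus a static anatomy line.

    The faint fixed line at row 25 breaks the vertical symmetry of the
    time-averaged profile, as static anatomy does in real shroud images.
    """
    rng = np.random.default_rng(seed)
    r = np.arange(n_rows)[:, None]
    mat = -np.exp(-0.5 * ((r - np.asarray(center_rows)[None, :]) / 4.0) ** 2)
    mat += -0.4 * np.exp(-0.5 * ((r - 25.0) / 3.0) ** 2)
    mat += rng.normal(0, noise_sd, mat.shape)
    return m.ASImage(
        matrix=mat, row_pitch_mm=0.2, frame_times=0.2 * np.arange(len(center_rows))
    )


class TestMakeASImage:
    def test_constant_frames_collapse_to_zero(self):
        stack = ProjectionStack(
            frames=np.full((5, 32, 16), 400.0, dtype=np.float32),
            times=0.2 * np.arange(5),
            angles=0.3 * np.arange(5),
            pixel_size_mm=0.2,
            imager=m.ImagerGeometry(1, 0.0),
        )
        img = m.make_as_image(stack)
        assert np.allclose(img.matrix, 0.0)
        assert img.n_frames == 5

    def test_column_extremum_tracks_the_edge(self):
        # narrow transition: the log-gradient extremum sits on the edge row
        edges = [100.0, 110.0, 127.5, 150.0]
        img = m.make_as_image(_stack_from_edges(edges, hw=1.5))
        for j, e in enumerate(edges):
            ridge = int(np.argmin(img.matrix[:, j]))
            assert abs(ridge - e) <= 1

    def test_ridge_traces_a_sinusoidal_edge(self):
        t = np.arange(120)
        edges = 127.5 + 30 * np.sin(2 * np.pi * t / 24)
        img = m.make_as_image(_stack_from_edges(edges))
        ridge = np.argmin(img.matrix, axis=0).astype(float)
        assert np.corrcoef(ridge, edges)[0, 1] > 0.99

    def test_nonpositive_pixels_need_offset(self):
        frames = np.full((3, 8, 8), -1.0, dtype=np.float32)
        stack = ProjectionStack(
            frames=frames,
            times=0.2 * np.arange(3),
            angles=np.zeros(3),
            pixel_size_mm=0.2,
            imager=m.ImagerGeometry(1, 0.0),
        )
        with pytest.raises(ValueError, match="non-positive"):
            m.make_as_image(stack)
        img = m.make_as_image(stack, log_offset=10.0)
        assert np.allclose(img.matrix, 0.0)


class TestSuperimpose:
    def test_self_superimposition_is_identity(self):
        img = _ridge_image(60 + 10 * np.sin(np.linspace(0, 6, 80)))
        out = m.superimpose_as(img, img)
        assert np.allclose(out.matrix, img.matrix)
        assert out.provenance == "dual"

    def test_recovers_row_shift(self):
        base = _ridge_image(60 + 10 * np.sin(np.linspace(0, 6, 80)))
        shifted = m.ASImage(
            matrix=np.roll(base.matrix, 7, axis=0),
            row_pitch_mm=0.2,
            frame_times=base.frame_times,
        )
        out = m.superimpose_as(base, shifted)
        # overlap equals the first image exactly
        assert np.allclose(out.matrix[:-7], base.matrix[:-7])

    def test_shift_recovery_under_noise(self):
        """Exhaustive correlation search finds the true shift despite noise."""
        rng_edges = 60 + 10 * np.sin(np.linspace(0, 9, 120))
        for true_shift in (-20, -7, 0, 13, 20):
            a = _ridge_image(rng_edges, noise_sd=0.2, seed=1)
            b_mat = np.roll(_ridge_image(rng_edges, noise_sd=0.2, seed=2).matrix,
                            true_shift, axis=0)
            b = m.ASImage(matrix=b_mat, row_pitch_mm=0.2, frame_times=a.frame_times)
            from as4dpm.shroud import _registration_shift
            s = _registration_shift(a.matrix.mean(axis=1), b.matrix.mean(axis=1), 30)
            # aligning the rolled image needs the opposite shift
            assert s == -true_shift

    def test_mismatched_shapes_rejected(self):
        a = _ridge_image(np.full(10, 60.0))
        b = _ridge_image(np.full(11, 60.0))
        with pytest.raises(ValueError):
            m.superimpose_as(a, b)


class TestTrim:
    def test_full_band_is_identity(self):
        img = _ridge_image(60 + 10 * np.sin(np.linspace(0, 6, 40)))
        out = m.trim_as(img, (0, img.n_rows))
        assert np.array_equal(out.matrix, img.matrix)

    def test_zero_margin_keeps_single_row(self):
        img = _ridge_image(np.full(10, 60.0) + np.arange(10) * 0.5)
        out = m.trim_as(img, "auto", margin=0)
        assert out.n_rows == 1

    def test_auto_center_lies_in_the_excursion(self, clean_case):
        img = m.make_as_image(clean_case.projections[0])
        out = m.trim_as(img, "auto")
        d = clean_case.diaphragm.values / 0.2 + 127.5
        center = out.row_offset + out.n_rows // 2
        assert d.min() - 1 <= center <= d.max() + 1

    def test_empty_band_rejected(self):
        img = _ridge_image(np.full(5, 60.0))
        with pytest.raises(ValueError, match="empty"):
            m.trim_as(img, (50, 50))


class TestLocalNormalize:
    def test_constant_image_stays_constant(self):
        img = m.ASImage(
            matrix=np.full((40, 30), 3.3),
            row_pitch_mm=0.2,
            frame_times=0.2 * np.arange(30),
        )
        out = m.local_normalize(img, window=5)
        assert np.allclose(out.matrix, out.matrix.flat[0])

    def test_window_validation(self):
        img = _ridge_image(np.full(10, 60.0))
        with pytest.raises(ValueError):
            m.local_normalize(img, window=4)
        with pytest.raises(ValueError):
            m.local_normalize(img, window=999)

    def test_illumination_ramp_invariance(self, clean_case):
        """A linear intensity ramp changes the output by < 5 % RMS."""
        img = m.trim_as(m.make_as_image(clean_case.projections[0]), "support")
        ramp = np.linspace(0, 2 * img.matrix.std(), img.n_rows)[:, None]
        ramped = m.ASImage(
            matrix=img.matrix + ramp,
            row_pitch_mm=img.row_pitch_mm,
            frame_times=img.frame_times,
        )
        out = m.local_normalize(img).matrix
        out_r = m.local_normalize(ramped).matrix
        rel = np.sqrt(np.mean((out - out_r) ** 2)) / np.sqrt(np.mean(out**2))
        assert rel < 0.05

    def test_tile_means_equalized(self, noisy_case):
        """Normalization makes tile-mean brightness substantially more
        uniform than in the raw shroud image."""

        def tile_cv(mat):
            tile = max(8, mat.shape[0] // 8)
            means = np.asarray(
                [
                    mat[i : i + tile, j : j + tile].mean()
                    for i in range(0, mat.shape[0] - tile + 1, tile)
                    for j in range(0, mat.shape[1] - tile + 1, tile)
                ]
            )
            return means.std() / means.mean()

        img = m.trim_as(m.make_as_image(noisy_case.projections[0]), "support")
        raw = (img.matrix - img.matrix.min()) / np.ptp(img.matrix)
        cv_norm = tile_cv(m.local_normalize(img).matrix)
        assert cv_norm < 0.2
        assert cv_norm < 0.6 * tile_cv(raw)


class TestExtractWaveform:
    def test_noiseless_waveform_tracks_the_diaphragm(self, clean_case):
        wav = m.shroud_waveform(clean_case.projections)
        r = np.corrcoef(wav.samples, clean_case.diaphragm.values)[0, 1]
        assert r > 0.99

    def test_zero_variance_image_rejected(self):
        img = m.ASImage(
            matrix=np.ones((20, 2)),
            row_pitch_mm=0.2,
            frame_times=np.array([0.0, 0.2]),
        )
        with pytest.raises(ValueError, match="zero-variance"):
            m.extract_as_waveform(img)

    def test_global_intensity_scaling_is_immaterial(self, clean_case):
        """x2 brighter frames yield the identical waveform (log-gradient)."""
        stack = clean_case.projections[0]
        doubled = ProjectionStack(
            frames=stack.frames * 2.0,
            times=stack.times,
            angles=stack.angles,
            pixel_size_mm=stack.pixel_size_mm,
            imager=stack.imager,
        )
        w1 = m.shroud_waveform(stack)
        w2 = m.shroud_waveform(doubled)
        assert np.allclose(w1.samples, w2.samples, atol=1e-10)

    def test_dual_not_worse_than_either_single(self, schedule):
        """Superimposition never degrades fidelity beyond estimation noise."""
        truth_r = []
        for seed in (2, 3):
            case = m.simulate_case(m.BreathingParams(seed=seed), schedule)
            truth = case.diaphragm.values
            r_dual = np.corrcoef(
                m.shroud_waveform(case.projections).samples, truth
            )[0, 1]
            r_singles = [
                np.corrcoef(m.shroud_waveform(p).samples, truth)[0, 1]
                for p in case.projections
            ]
            assert r_dual >= min(r_singles) - 0.005
            truth_r.append(r_dual)
        assert min(truth_r) > 0.95

    def test_pipeline_is_deterministic(self, noisy_case):
        w1 = m.shroud_waveform(noisy_case.projections)
        w2 = m.shroud_waveform(noisy_case.projections)
        assert w1.samples.tobytes() == w2.samples.tobytes()
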