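"""Generator tests: movie statistics, planted structure, determinism."""
import numpy as np
import pytest

from colliclust.config import SessionConfig
from colliclust import synthgen as sg


def radial_power_slope(frames: np.ndarray) -> float:
    """Independent periodogram oracle: log-log slope of the radially
    averaged spatial power spectrum, averaged over a few frames."""
    power = np.mean(
        [np.abs(np.fft.fft2(frames[:, :, t])) ** 2
         for t in range(0, frames.shape[2], 7)], axis=0)
    power = np.fft.fftshift(power)
    h, w = frames.shape[:2]
    fy = np.fft.fftshift(np.fft.fftfreq(h))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(w))[None, :]
    r = np.hypot(fy, fx).ravel()
    p = power.ravel()
    bins = np.logspace(np.log10(0.04), np.log10(0.45), 14)
    idx = np.digitize(r, bins)
    xs, ys = [], []
    for b in range(1, len(bins)):
        m = idx == b
        if m.sum() > 3:
            xs.append(np.log10(r[m].mean()))
            ys.append(np.log10(p[m].mean()))
    return float(np.polyfit(xs, ys, 1)[0])


class TestMovies:
    def test_deterministic_under_seed(self):
        cfg = SessionConfig(seed=0, movie_duration_s=5.0)
        a = sg.generate_movies(cfg)
        b = sg.generate_movies(cfg)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.frames, mb.frames)

    def test_luminance_range_and_count(self):
        movies = sg.generate_movies(SessionConfig(seed=1, movie_duration_s=5.0))
        assert len(movies) == 4
        assert {m.name for m in movies} == set(sg.MOVIE_NAMES)
        for m in movies:
            assert m.frames.min() >= 0.0 and m.frames.max() <= 1.0
            assert m.frames.shape[2] >= 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_spatial_spectrum_near_one_over_f_squared(self, seed):
        movies = sg.generate_movies(SessionConfig(seed=seed))
        for m in movies:
            slope = radial_power_slope(m.frames)
            assert slope == pytest.approx(-2.0, abs=0.3), m.name

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            sg.generate_movies(SessionConfig(movie_height_px=4))


class TestMovieStats:
    def test_constant_movie_zero_contrast_and_motion(self):
        frames = np.full((8, 8, 5), 0.5)
        m = sg.MovieStimulus(frames, 4.8, "const", 1.0)
        stats = sg.movie_stats(m)
        assert np.allclose(stats.rms_contrast, 0.0)
        assert np.allclose(stats.motion_energy.iloc[1:], 0.0)

    def test_unit_step_motion_energy(self):
        frames = np.stack([np.zeros((6, 6)), np.ones((6, 6))], axis=2)
        stats = sg.movie_stats(sg.MovieStimulus(frames, 4.8, "step", 1.0))
        assert stats.motion_energy.iloc[1] == pytest.approx(1.0)

    def test_checkerboard_rms_contrast_one(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        frames = np.repeat(board[:, :, None].astype(float), 3, axis=2)
        stats = sg.movie_stats(sg.MovieStimulus(frames, 4.8, "check", 1.0))
        # mean 0.5, SD 0.5 -> RMS contrast exactly 1
        assert np.allclose(stats.rms_contrast, 1.0)

    def test_zero_frame_flags_contrast(self):
        frames = np.zeros((6, 6, 3))
        frames[:, :, 1] = 0.5
        with pytest.warns(UserWarning, match="contrast"):
            stats = sg.movie_stats(sg.MovieStimulus(frames, 4.8, "z", 1.0))
        assert np.isnan(stats.rms_contrast.iloc[0])


class TestPopulation:
    def test_counts(self):
        cfg = SessionConfig(n_clusters=16, neurons_per_cluster=200,
                            n_unresponsive=0)
        pop = sg.generate_population(cfg)
        assert len(pop) == 3200

    def test_compact_cluster_rf_disc_under_900_deg2(self, tiny_config):
        pop = sg.generate_population(tiny_config)
        df = sg.population_frame(pop)
        for c in range(tiny_config.n_compact_clusters):
            sub = df[df.cluster_id == c]
            center = sub[["rf_az", "rf_el"]].mean()
            r = np.hypot(sub.rf_az - center.rf_az, sub.rf_el - center.rf_el)
            assert np.pi * r.max() ** 2 < 900.0

    def test_compact_anatomy_tighter_than_full_field(self, tiny_config):
        df = sg.population_frame(sg.generate_population(tiny_config))

        def median_pairdist(sub):
            xy = sub[["x_um", "y_um"]].to_numpy()
            d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).T)
            return np.median(d[np.triu_indices(len(xy), 1)])

        compact = median_pairdist(df[df.cluster_id == 0])
        full = median_pairdist(df[df.cluster_id == tiny_config.n_clusters - 1])
        assert compact < full


class TestSimulation:
    def test_deterministic_store(self, tiny_config, tiny_session):
        again = sg.generate_session(tiny_config)
        for name, block in tiny_session.blocks.items():
            np.testing.assert_array_equal(block.traces, again.blocks[name].traces)
            np.testing.assert_array_equal(block.neuropil,
                                          again.blocks[name].neuropil)

    def test_noiseless_repetitions_identical(self, noiseless_session):
        for block in noiseless_session.blocks.values():
            first = block.traces[:, :, 0]
            for rep in range(1, block.traces.shape[2]):
                if block.name == "looming":
                    continue  # habituation scales repetitions by design
                np.testing.assert_allclose(block.traces[:, :, rep], first,
                                           rtol=1e-6)

    def test_fully_selective_neuron_single_direction(self):
        cfg = SessionConfig(n_clusters=2, neurons_per_cluster=5, seed=9,
                            noise_sd=0.0, drift_amp=0.0,
                            movie_duration_s=5.0, n_unresponsive=0,
                            out_of_bounds_fraction=0.0)
        pop = sg.generate_population(cfg)
        pop[0].dsi_true = 1.0
        movies = sg.generate_movies(cfg)
        sess = sg.simulate_session(pop, movies, config=cfg)
        block = sess.blocks["bar"]
        fr = block.frame_rate
        # somatic drive: neuropil-corrected, baseline-subtracted
        corrected = block.traces[0, :, 0] - 0.7 * block.neuropil[0, :, 0]
        trace = corrected - corrected.min()
        peaks = []
        for seg in block.schedule["segments"]:
            s0 = int(round(seg["t0"] * fr))
            s1 = int(round(seg["t1"] * fr))
            peaks.append(trace[s0:s1].max())
        peaks = np.array(peaks)
        best = np.argmax(peaks)
        assert peaks[best] > 0.1
        # the calcium kernel tail may leak into the next sweep window; all
        # other windows are exactly silent
        tail = (best + 1) % len(peaks)
        others = np.delete(peaks, [best, tail])
        assert np.all(others < 1e-6)  # float32 storage quantization
        assert peaks[tail] < 0.15 * peaks[best]

    def test_sparse_noise_peak_at_planted_square(self, noiseless_session):
        block = noiseless_session.blocks["sparse_noise"]
        sched = block.schedule
        pre = sched["pre_samples"]
        n_sq = sched["n_squares"]
        centers = sg.sparse_grid_centers()
        gt = noiseless_session.ground_truth
        tm = block.traces.mean(axis=2)
        for i in range(len(gt)):
            m = tm[i, pre:pre + n_sq]
            best = centers[np.argmax(m)]
            # the peak square contains (or abuts, for elliptical RFs whose
            # metric differs from Euclidean) the planted center
            assert abs(best[0] - gt.rf_az[i]) <= 5.0 + 1e-9
            assert abs(best[1] - gt.rf_el[i]) <= 5.0 + 1e-9

    def test_between_cluster_distance_monotone_in_separation(self):
        stats = []
        for sep in (1.0, 3.0, 6.0):
            cfg = SessionConfig(n_clusters=3, neurons_per_cluster=15, seed=11,
                                cluster_separation=sep, movie_duration_s=5.0,
                                n_unresponsive=0, noise_sd=0.0, drift_amp=0.0)
            sess = sg.generate_session(cfg)
            gt = sess.ground_truth
            traces = np.concatenate(
                [sess.blocks[f"movie_{n}"].traces[:, :, 0]
                 for n in sg.MOVIE_NAMES], axis=1)
            means = np.stack([traces[gt.cluster_id == c].mean(axis=0)
                              for c in range(3)])
            within = np.mean([traces[gt.cluster_id == c].std(axis=0).mean()
                              for c in range(3)])
            between = np.mean([np.linalg.norm(means[a] - means[b])
                               for a in range(3) for b in range(a + 1, 3)])
            stats.append(between / within)
        assert stats[0] < stats[1] < stats[2]

    def test_frame_rate_mismatch_rejected(self, tiny_config):
        movies = sg.generate_movies(tiny_config)
        pop = sg.generate_population(tiny_config)
        movies[0].frame_rate = 30.0
        with pytest.raises(ValueError):
            sg.simulate_session(pop, movies, config=tiny_config)
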