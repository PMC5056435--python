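"""Generator: state paths, traces, movies, dwell samples."""

import warnings

import numpy as np
import pytest
from scipy import stats

import sifa
from sifa import synthetic as syn


class TestStatePath:
    def test_single_state_never_jumps(self):
        path = syn.simulate_state_path(syn.single_state_model(4.0), 10.0, seed=0)
        assert len(path.states) == 1
        assert path.state_at([0.1, 5.0, 9.9]).tolist() == [0, 0, 0]

    def test_two_state_dwells_have_exponential_mean(self):
        """Symmetric two-state chain at rate k: dwell mean 1/k within 2%.

        Dwells are taken from the start of one very long path so the fixed
        observation window never length-biases the sample (complete dwells
        inside a short window are systematically the shorter ones)."""
        k = 5.0
        model = syn.StateModel(
            positions=(3.0, 5.0), position_sds=(0.1, 0.1),
            rates=((-k, k), (k, -k)), bleach_rate=0.0,
        )
        path = syn.simulate_state_path(model, 10_000.0, seed=1)
        dwells = path.dwell_times()[:20_000]  # spans ~4,000 s of the window
        assert len(dwells) == 20_000
        assert dwells.mean() == pytest.approx(1.0 / k, rel=0.02)

    def test_occupancy_matches_stationary_distribution(self):
        """Time-weighted occupancy of a long run agrees with the rate
        matrix's stationary eigenvector (total variation < 0.02)."""
        model = syn.five_state_model(bleach_rate=0.0)
        duration = 1e6 / 30.0  # a million frames of footage
        path = syn.simulate_state_path(model, duration, seed=7)
        occ = np.zeros(model.n_states)
        np.add.at(occ, path.states, path.dwell_times())
        occ /= occ.sum()
        pi = syn.stationary_distribution(model)
        assert 0.5 * np.abs(occ - pi).sum() < 0.02

    def test_invalid_rate_matrix_rejected(self):
        with pytest.raises(ValueError):
            syn.StateModel(
                positions=(1.0, 2.0), position_sds=(0.1, 0.1),
                rates=((-1.0, 2.0), (1.0, -1.0)),
            )
        with pytest.raises(ValueError):
            syn.StateModel(
                positions=(2.0, 1.0), position_sds=(0.1, 0.1),
                rates=((-1.0, 1.0), (1.0, -1.0)),
            )


class TestTraceEmission:
    def test_noise_free_single_state_at_d0_is_constant(self):
        quench = sifa.QuenchModel(d0=4.0, i0=1000.0)
        noise = syn.NoiseModel(background_mean=100.0, background_sd=0.0, gain_sd_fraction=0.0)
        model = syn.single_state_model(4.0, sd=0.0)
        path = syn.simulate_state_path(model, 2.0, seed=0)
        trace, _ = syn.simulate_trace(path, model, quench, noise, seed=0)
        assert np.allclose(trace.intensity, 0.5 * 1000.0 + 100.0)

    def test_noise_free_emission_lies_on_quench_curve(self):
        quench = sifa.QuenchModel(d0=4.0, i0=1000.0)
        noise = syn.NoiseModel(background_mean=0.0, background_sd=0.0, gain_sd_fraction=0.0)
        model = syn.five_state_model(bleach_rate=0.0)
        path = syn.simulate_state_path(model, 5.0, seed=3)
        trace, truth = syn.simulate_trace(path, model, quench, noise, seed=3)
        expected = 1000.0 * sifa.relative_intensity(truth.height_nm, quench)
        assert np.allclose(trace.intensity, expected)

    def test_mean_trace_length_follows_bleach_rate(self):
        """bleach_rate 0.1/s: mean live length matches the truncated
        exponential mean over 4,000 traces (a 5% band is ~3 standard
        errors at this sample size)."""
        quench = sifa.QuenchModel(d0=4.0, i0=1000.0)
        noise = syn.NoiseModel()
        model = syn.single_state_model(4.0, sd=0.1, bleach_rate=0.1)
        traces, _ = syn.simulate_traces(model, quench, noise, 4000, 20.0, seed=5)
        lives = [len(t.live_intensity()) * t.frame_interval for t in traces]
        expected = 10.0 * (1.0 - np.exp(-2.0))  # E[min(Exp(0.1), 20 s)]
        assert np.mean(lives) == pytest.approx(expected, rel=0.05)

    def test_post_bleach_frames_are_background_only(self):
        quench = sifa.QuenchModel(d0=4.0, i0=1000.0)
        noise = syn.NoiseModel(background_mean=50.0, background_sd=0.0, gain_sd_fraction=0.0)
        model = syn.single_state_model(4.0, sd=0.0, bleach_rate=2.0)
        path = syn.simulate_state_path(model, 20.0, seed=11)
        trace, truth = syn.simulate_trace(path, model, quench, noise, seed=11)
        assert trace.bleach_index is not None
        assert np.allclose(trace.intensity[trace.bleach_index:], 50.0)
        assert np.all(np.isnan(truth.height_nm[trace.bleach_index:]))

    def test_seed_reproducibility(self):
        cfg = sifa.RunConfig(seed=9, n_traces=3, duration_s=5.0)
        a, _ = syn.simulate_traces(cfg.state_model(), cfg.quench_model(), cfg.noise_model(), 3, 5.0, seed=9)
        b, _ = syn.simulate_traces(cfg.state_model(), cfg.quench_model(), cfg.noise_model(), 3, 5.0, seed=9)
        c, _ = syn.simulate_traces(cfg.state_model(), cfg.quench_model(), cfg.noise_model(), 3, 5.0, seed=10)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.intensity, tb.intensity)
        assert not np.array_equal(a[0].intensity, c[0].intensity)


class TestCompositeDwells:
    def test_bright_state_dwells_follow_two_exponential_mixture(self):
        """In the GO-supported model the composite bright dwell is by
        construction a 50/50 mixture of 60 and 260 ms exponentials
        (Kolmogorov-Smirnov against the analytic CDF, 10,000 dwells)."""
        model = syn.two_state_go_model()
        rng = np.random.default_rng(21)
        dwells = []
        while len(dwells) < 10_000:
            path = syn.simulate_state_path(model, 2000.0, rng)
            edges = np.append(path.jump_times, path.duration)
            bright = np.isin(path.states, (1, 2))
            # merge contiguous bright intervals (none exist by construction,
            # but keep the extraction general)
            durations = np.diff(edges)[bright]
            inner = bright.copy()
            inner[0] = inner[-1] = False  # censor path-boundary dwells
            dwells.extend(np.diff(edges)[inner])
        dwells = np.asarray(dwells[:10_000])
        cdf = lambda t: sifa.double_exp_cdf(t, 0.5, 0.060, 0.260)
        assert stats.kstest(dwells, cdf).pvalue > 0.01

    def test_dwell_mixture_sampler_mean(self):
        d = syn.sample_dwell_mixture(50_000, 0.060, 0.260, 0.5, seed=2)
        assert d.mean() == pytest.approx(0.5 * (0.060 + 0.260), rel=0.02)


class TestMovie:
    def test_photometry_conservation_single_noiseless_spot(self):
        """With noise off, every frame's total equals the emitted amplitude
        plus the flat background."""
        quench = sifa.QuenchModel(d0=4.0, i0=1000.0)
        noise = syn.NoiseModel(background_sd=0.0, gain_sd_fraction=0.0)
        model = syn.single_state_model(4.0, sd=0.0, bleach_rate=0.0)
        movie, truths = syn.simulate_movie(
            model, quench, noise, n_spots=1, n_frames=5, shape=(64, 64),
            seed=0, background_per_px=2.0, poisson_noise=False,
        )
        expected = truths[0].amplitude + 2.0 * 64 * 64
        assert np.allclose(movie.sum(axis=(1, 2)), expected, rtol=1e-9)

    def test_overlapping_spots_warn(self):
        quench = sifa.QuenchModel(d0=4.0, i0=1000.0)
        model = syn.single_state_model(4.0, sd=0.0, bleach_rate=0.0)
        with pytest.warns(UserWarning, match="PSF"):
            syn.simulate_movie(
                model, quench, syn.NoiseModel(), n_spots=16, n_frames=2,
                shape=(48, 48), seed=0, psf_sigma=2.5,
            )

    def test_movie_seed_reproducibility(self):
        quench = sifa.QuenchModel(d0=4.0, i0=1000.0)
        model = syn.five_state_model()
        a, _ = syn.simulate_movie(model, quench, syn.NoiseModel(), 4, 10, (64, 64), seed=3)
        b, _ = syn.simulate_movie(model, quench, syn.NoiseModel(), 4, 10, (64, 64), seed=3)
        assert np.array_equal(a, b)


def test_csv_round_trip(tmp_path):
    cfg = sifa.RunConfig(seed=2, n_traces=2, duration_s=3.0)
    traces, truths = syn.simulate_traces(
        cfg.state_model(), cfg.quench_model(), cfg.noise_model(), 2, 3.0, seed=2
    )
    path = tmp_path / "traces.csv"
    syn.write_traces_csv(path, traces, truths)
    back = syn.read_traces_csv(path)
    assert len(back) == 2
    assert np.allclose(back[0].intensity, traces[0].intensity)
    assert back[0].bleach_index == traces[0].bleach_index
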