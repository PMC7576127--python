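import numpy as np
import pytest
from scipy import stats

import hyperspike as hs


class TestPoissonSpikes:
    def test_counts_match_poisson_at_rate_1(self):
        # mean 500 at rate 1 Hz x 500 s; +/-3 sigma band [433, 567] should
        # hold for ~99.7% of seeds (allow the binomial tail)
        counts = np.array([len(hs.generate_spike_train(1.0, 500.0, seed))
                           for seed in range(1000)])
        outside = np.sum((counts < 433) | (counts > 567))
        assert outside <= 10
        assert abs(counts.mean() - 500.0) < 5.0

    def test_isi_distribution_is_exponential(self):
        st = hs.generate_spike_train(5.0, 2200.0, seed=7)
        isi = np.diff(st.times)[:10000]
        assert isi.size == 10000
        _, p = stats.kstest(isi, "expon", args=(0, 1.0 / 5.0))
        assert p > 0.01

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            hs.generate_spike_train(1.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            hs.generate_spike_train(0.0, 1.0, seed=0)


class TestAlphaNonlinearity:
    @pytest.mark.parametrize("v,alpha,expected", [
        (1.0, 0.5, 1.0),   # boundary: 1**alpha == 1
        (2.0, 1.0, 2.0),   # identity exponent
        (4.0, 0.5, 2.0),   # analytic square root
        (0.5, 3.0, 0.5),   # below threshold untouched
        (-0.2, 2.0, -0.2),
    ])
    def test_pointwise(self, v, alpha, expected):
        assert hs.apply_alpha_nonlinearity(v, alpha) == pytest.approx(expected)

    def test_continuous_at_one(self):
        eps = 1e-9
        lo = hs.apply_alpha_nonlinearity(1.0 - eps, 2.5)
        hi = hs.apply_alpha_nonlinearity(1.0 + eps, 2.5)
        assert abs(hi - lo) < 1e-8

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            hs.apply_alpha_nonlinearity(np.array([1.0, np.inf]), 2.0)


class TestSynthesizeTrace:
    def setup_method(self):
        self.cfg = hs.SimulationConfig(tau1=0.05, tau2=0.4, sampling_rate=1000.0,
                                       snr=5.0, seed=0)
        self.model = self.cfg.model()

    def test_empty_train_noiseless_is_baseline(self):
        model = hs.CaSpikeModel(tau1=0.01, tau2=0.5, amplitude_a=1.0,
                                baseline_b0=0.7)
        tr = hs.synthesize_trace(hs.SpikeTrain([]), model, alpha=1.0, snr=5.0,
                                 sampling_rate=30.0, duration=5.0, seed=None)
        assert np.allclose(tr.values, 0.7)

    def test_single_spike_peak_location(self):
        # dense grid argmax at ~0.110 s = tau1*log((tau1+tau2)/tau1)
        tr = hs.synthesize_trace(hs.SpikeTrain([0.0]), self.model, alpha=1.0,
                                 snr=5.0, sampling_rate=1000.0, duration=2.0,
                                 seed=None)
        peak_t = np.argmax(tr.values) / 1000.0
        assert np.isclose(peak_t, 0.05 * np.log(9.0), atol=2e-3)

    def test_noise_sd_matches_snr(self):
        spikes = hs.SpikeTrain([])
        model = hs.CaSpikeModel(tau1=0.01, tau2=0.5, amplitude_a=1.0)
        noisy = hs.synthesize_trace(spikes, model, alpha=1.0, snr=5.0,
                                    sampling_rate=1000.0, duration=100.0, seed=3)
        clean = hs.synthesize_trace(spikes, model, alpha=1.0, snr=5.0,
                                    sampling_rate=1000.0, duration=100.0, seed=None)
        sd = np.std(noisy.values - clean.values)
        assert np.isclose(sd, model.peak_amplitude / 5.0, rtol=0.02)

    def test_spikes_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            hs.synthesize_trace(hs.SpikeTrain([10.0]), self.model, 1.0, 5.0,
                                30.0, 5.0)


class TestGenerateDataset:
    def test_expected_total_spike_count(self):
        cfg = hs.SimulationConfig(seed=11)  # 10 cells x 50 expected
        cells = hs.generate_dataset(cfg)
        total = sum(len(s) for _, s in cells)
        assert 433 <= total <= 567  # Poisson(500) +/- 3 sigma

    def test_determinism(self):
        cfg = hs.SimulationConfig(seed=4, n_cells=3, spikes_per_cell=10)
        a = hs.generate_dataset(cfg)
        b = hs.generate_dataset(cfg)
        for (t1, s1), (t2, s2) in zip(a, b):
            assert np.array_equal(t1.values, t2.values)
            assert np.array_equal(s1.times, s2.times)

    def test_split_halves(self):
        cfg = hs.SimulationConfig(seed=4)
        train, test = hs.generate_dataset(cfg, split=True)
        assert len(train) == len(test) == 5
        with pytest.raises(ValueError):
            hs.generate_dataset(hs.SimulationConfig(n_cells=1), split=True)

    def test_matches_linear_prediction_in_noiseless_linear_limit(self):
        cfg = hs.SimulationConfig(n_cells=1, spikes_per_cell=20, alpha=1.0,
                                  snr=1e6, sampling_rate=40.0, seed=9)
        (trace, spikes), = hs.generate_dataset(cfg)
        pred = hs.linear_prediction(spikes, cfg.model(), trace.frame_times())
        resid = trace.values - pred
        scale = np.abs(pred).max()
        assert np.max(np.abs(resid)) / scale < 1e-4

    def test_oracle_equivalence_alpha1_sigma0(self):
        # exact cross-module identity: simulator output == linear model
        cfg = hs.SimulationConfig(n_cells=1, spikes_per_cell=10,
                                  sampling_rate=25.0, seed=5)
        st = hs.generate_spike_train(1.0, cfg.duration, seed=0)
        trace = hs.synthesize_trace(st, cfg.model(), alpha=1.0, snr=5.0,
                                    sampling_rate=25.0, duration=cfg.duration,
                                    seed=None)
        pred = hs.linear_prediction(st, cfg.model(), trace.frame_times())
        assert np.allclose(trace.values, pred, atol=1e-12)

    def test_snr_monotonicity(self):
        cfg = hs.SimulationConfig(n_cells=1, spikes_per_cell=10,
                                  sampling_rate=30.0, seed=5)
        st = hs.generate_spike_train(1.0, cfg.duration, seed=1)
        clean = hs.synthesize_trace(st, cfg.model(), 1.0, 5.0, 30.0,
                                    cfg.duration, seed=None)
        prev = np.inf
        for snr in (3.0, 5.0, 10.0, 100.0):
            noisy = hs.synthesize_trace(st, cfg.model(), 1.0, snr, 30.0,
                                        cfg.duration, seed=42)
            mse = np.mean((noisy.values - clean.values) ** 2)
            assert mse < prev
            prev = mse
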