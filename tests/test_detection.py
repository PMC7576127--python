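import numpy as np
import pytest

import hyperspike as hs
from hyperspike.detection import (ConstantClassifier, label_window,
                                  optimize_detection)
from hyperspike.metrics import match_pairs


MODEL = hs.CaSpikeModel(tau1=0.01, tau2=0.5, amplitude_a=1.0)


def noiseless_trace(spike_times, rate=30.0, duration=20.0, model=MODEL):
    return hs.synthesize_trace(hs.SpikeTrain(spike_times), model, alpha=1.0,
                               snr=5.0, sampling_rate=rate, duration=duration,
                               seed=None)


class TestCoincidenceScore:
    def test_constant_trace_all_zero(self):
        tr = hs.CalciumTrace(np.full(600, 2.0), 30.0)
        assert np.allclose(hs.coincidence_score(tr, MODEL), 0.0)

    def test_peak_at_onset_frame(self):
        # frame-aligned onset: the global maximum sits exactly at the onset
        # frame; onsets late in a frame may score highest one frame later
        # because the first post-onset sample carries almost no rise
        tr = noiseless_trace([5.0])
        assert np.argmax(hs.coincidence_score(tr, MODEL)) == 150
        for onset in (5.012, 5.028):
            tr = noiseless_trace([onset])
            k = np.argmax(hs.coincidence_score(tr, MODEL))
            assert k in (150, 151)

    def test_offset_invariance(self):
        tr = noiseless_trace([5.0])
        shifted = hs.CalciumTrace(tr.values + 3.7, tr.sampling_rate)
        assert np.allclose(hs.coincidence_score(tr, MODEL),
                           hs.coincidence_score(shifted, MODEL), atol=1e-9)

    def test_short_trace_rejected(self):
        tr = hs.CalciumTrace(np.zeros(10), 30.0)
        with pytest.raises(ValueError, match="support"):
            hs.coincidence_score(tr, MODEL)


class TestExtractCandidates:
    def setup_method(self):
        self.config = hs.DetectionConfig(score_threshold=3.0, segment_pre=2,
                                         segment_post=4)

    def test_threshold_above_max_gives_empty(self):
        tr = noiseless_trace([5.0])
        sc = hs.coincidence_score(tr, MODEL)
        cfg = hs.DetectionConfig(score_threshold=float(sc.max()) + 1.0)
        assert hs.extract_candidates(tr, sc, cfg) == []

    def test_two_spikes_two_candidates(self):
        rng = np.random.default_rng(0)
        tr = noiseless_trace([5.0, 10.0])
        vals = tr.values + rng.normal(0, 0.01, tr.n_frames)
        tr = hs.CalciumTrace(vals, tr.sampling_rate)
        sc = hs.coincidence_score(tr, MODEL)
        cands = hs.extract_candidates(tr, sc, self.config,
                                      truth=hs.SpikeTrain([5.0, 10.0]))
        spikes = [c for c in cands if c.label == "spike"]
        assert len(spikes) == 2
        assert sorted(int(c.pt * 30) for c in spikes) == [150, 300]

    def test_edge_padding_keeps_fixed_length(self):
        tr = noiseless_trace([0.02])
        sc = hs.coincidence_score(tr, MODEL)
        cfg = hs.DetectionConfig(score_threshold=1.0, segment_pre=3,
                                 segment_post=4)
        cands = hs.extract_candidates(tr, sc, cfg)
        assert cands and all(c.frames.size == cfg.segment_length for c in cands)


class TestOptimizeDetection:
    def make_train_cells(self, n=2, seed=0):
        cfg = hs.SimulationConfig(firing_rate=1.0, tau2=0.5, snr=10.0,
                                  sampling_rate=30.0, n_cells=n,
                                  spikes_per_cell=25, seed=seed)
        return hs.generate_dataset(cfg), cfg.model()

    def test_noiseless_threshold_admits_all_spikes(self):
        st = hs.SpikeTrain(np.arange(1.0, 19.0, 2.5))
        tr = noiseless_trace(st.times)
        cfg = optimize_detection([(tr, st)], MODEL)
        sc = hs.coincidence_score(tr, MODEL)
        cands = hs.extract_candidates(tr, sc, cfg)
        pts = np.array([c.pt for c in cands])
        pairs = match_pairs(st.times, pts, label_window(tr.sampling_rate))
        assert len(pairs) == len(st)  # candidate-level sensitivity 1.0

    def test_single_config_grid_returned_unchanged(self):
        cells, model = self.make_train_cells()
        cfg = optimize_detection(cells, model, thresholds=(2.0,),
                                 pre_grid=(2,), post_grid=(4,))
        assert (cfg.score_threshold, cfg.segment_pre, cfg.segment_post) \
            == (2.0, 2, 4)

    def test_tie_broken_to_lower_threshold(self):
        # two thresholds between the decay-shoulder level and the peak score
        # produce identical candidate sets, hence identical F1: a tie
        st = hs.SpikeTrain(np.arange(1.0, 19.0, 2.5))
        tr = noiseless_trace(st.times)
        sc = hs.coincidence_score(tr, MODEL)
        peak = sc.max()
        cfg = optimize_detection([(tr, st)], MODEL,
                                 thresholds=(0.5 * peak, 0.7 * peak),
                                 objective="candidates")
        assert cfg.score_threshold == pytest.approx(0.5 * peak)

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            optimize_detection([], MODEL)


class TestClassifier:
    def make_candidates(self, n_each=30, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        cands = []
        for label, amp in (("spike", 1.0), ("non-spike", 0.0)):
            for _ in range(n_each):
                frames = amp * np.array([0.1, 0.9, 0.7, 0.5]) \
                    + noise * rng.normal(size=4)
                scores = amp * np.array([3.0, 4.0, 1.0, 0.3]) \
                    + noise * rng.normal(size=4)
                cands.append(hs.CandidateSegment(frames=frames, scores=scores,
                                                 pt=0.0, frame_index=0,
                                                 label=label))
        return cands

    def test_separable_set_perfect_training_accuracy(self):
        cands = self.make_candidates()
        clf = hs.train_classifier(cands)
        labels = hs.classify(clf, cands)
        assert labels == [c.label for c in cands]

    def test_empty_prediction(self):
        clf = hs.train_classifier(self.make_candidates())
        assert hs.classify(clf, []) == []

    def test_single_class_rejected_or_constant(self):
        cands = [c for c in self.make_candidates() if c.label == "spike"]
        with pytest.raises(ValueError):
            hs.train_classifier(cands)
        clf = hs.train_classifier(cands, allow_constant=True)
        assert isinstance(clf, ConstantClassifier)
        assert hs.classify(clf, cands[:3]) == ["spike"] * 3

    def test_feature_length_mismatch_rejected(self):
        clf = hs.train_classifier(self.make_candidates())
        bad = hs.CandidateSegment(frames=np.zeros(7), scores=np.zeros(7),
                                  pt=0.0, frame_index=0)
        with pytest.raises(ValueError, match="feature length"):
            hs.classify(clf, [bad])

    def test_training_set_accuracy_on_simulated_candidates(
            self, reference_pipeline, reference_condition):
        _, train_cells, _ = reference_condition
        res = reference_pipeline
        cands = []
        for trace, truth in train_cells:
            sc = hs.coincidence_score(trace, res.model)
            cands.extend(hs.extract_candidates(trace, sc, res.detection,
                                               truth=truth))
        labels = hs.classify(res.classifier, cands)
        acc = np.mean([l == c.label for l, c in zip(labels, cands)])
        assert acc >= 0.9


class TestCandidateSensitivityBound:
    def test_classifier_only_removes_candidates(self, reference_pipeline,
                                                reference_condition):
        _, _, test_cells = reference_condition
        res = reference_pipeline
        for trace, truth in test_cells:
            sc = hs.coincidence_score(trace, res.model)
            cands = hs.extract_candidates(trace, sc, res.detection)
            pts_all = np.array([c.pt for c in cands])
            labels = hs.classify(res.classifier, cands)
            pts_kept = np.array([c.pt for c, l in zip(cands, labels)
                                 if l == "spike"])
            w = label_window(trace.sampling_rate)
            hits_all = len(match_pairs(truth.times, pts_all, w))
            hits_kept = len(match_pairs(truth.times, pts_kept, w))
            assert hits_kept <= hits_all
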