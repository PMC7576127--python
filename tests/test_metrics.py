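import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hyperspike as hs
from hyperspike.metrics import index_window, match_pairs
from oracles import edit_distance, optimal_matching, triangle_overlap_score


def train(times):
    return hs.SpikeTrain(np.sort(np.asarray(times, dtype=float)))


class TestMatchSpikes:
    def test_identical(self):
        h, m, fp, errs = hs.match_spikes(train([1, 2, 3]), train([1, 2, 3]), 0.05)
        assert (h, m, fp) == (3, 0, 0)
        assert np.allclose(errs, 0.0)

    def test_outside_window(self):
        h, m, fp, _ = hs.match_spikes(train([1.0]), train([1.2]), 0.05)
        assert (h, m, fp) == (0, 1, 1)

    def test_tie_breaks_to_earlier_truth(self):
        h, m, fp, errs = hs.match_spikes(train([1.00, 1.04]), train([1.02]), 0.05)
        assert (h, m, fp) == (1, 1, 0)
        assert errs[0] == pytest.approx(+0.02)  # paired with truth 1.00

    def test_greedy_counterexample_handled_optimally(self):
        # nearest-first greedy would find only one hit here
        h, m, fp, _ = hs.match_spikes(train([0.0, 0.5]), train([0.4, 0.9]), 0.45)
        assert h == 2

    def test_against_enumeration_oracle(self, rng):
        for _ in range(300):
            n, m = rng.integers(0, 7), rng.integers(0, 7)
            t = np.sort(rng.uniform(0, 3, n))
            e = np.sort(rng.uniform(0, 3, m))
            w = rng.uniform(0.05, 0.8)
            hits, _, _, errs = hs.match_spikes(train(t), train(e), w)
            o_hits, o_cost = optimal_matching(t, e, w)
            assert hits == o_hits
            assert np.isclose(sum(abs(x) for x in errs), o_cost, atol=1e-9)

    def test_sensitivity_monotone_under_deletion(self, rng):
        t = np.sort(rng.uniform(0, 10, 8))
        e = np.sort(rng.uniform(0, 10, 8))
        h_all, m_all, _, _ = hs.match_spikes(train(t), train(e), 0.5)
        for k in range(len(e)):
            h, m, _, _ = hs.match_spikes(train(t), train(np.delete(e, k)), 0.5)
            assert h <= h_all


class TestRocScores:
    @pytest.mark.parametrize("h,m,fp,expected", [
        (1, 0, 0, (1.0, 1.0, 1.0)),
        (8, 2, 2, (0.8, 0.8, 0.8)),
        (0, 5, 0, (0.0, 0.0, 0.0)),
        (0, 0, 3, (0.0, 0.0, 0.0)),
    ])
    def test_printed_formulas(self, h, m, fp, expected):
        assert hs.roc_scores(h, m, fp) == pytest.approx(expected)


class TestSpikeDistance:
    def test_identical_capped_inverse(self):
        d, inv = hs.spike_distance(train([1, 2]), train([1, 2]), 0.05)
        assert d == 0.0
        assert inv == 100.0

    def test_single_shift(self):
        # q = 20/s, shift cost 20*0.02 = 0.4, normalized by 1 truth spike
        d, inv = hs.spike_distance(train([1.0]), train([1.02]), 0.05)
        assert d == pytest.approx(0.4)
        assert inv == pytest.approx(2.5)

    def test_deletions_only(self):
        d, _ = hs.spike_distance(train([1.0, 2.0]), train([]), 0.05)
        assert d == pytest.approx(1.0)

    def test_empty_truth_unnormalized(self):
        d, _ = hs.spike_distance(train([]), train([1.0, 2.0]), 0.05)
        assert d == pytest.approx(2.0)

    def test_against_enumeration_oracle(self, rng):
        for _ in range(300):
            n, m = rng.integers(0, 5), rng.integers(0, 5)
            t = np.sort(rng.uniform(0, 2, n))
            e = np.sort(rng.uniform(0, 2, m))
            w = rng.uniform(0.05, 0.5)
            d, _ = hs.spike_distance(train(t), train(e), w)
            raw = d * n if n else d
            assert np.isclose(raw, edit_distance(t, e, 1.0 / w), atol=1e-9)


class TestCosmic:
    def test_identical(self):
        assert hs.cosmic(train([1, 2, 5]), train([1, 2, 5]), 0.05) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint(self):
        assert hs.cosmic(train([0.0]), train([1.0]), 0.05) == 0.0

    def test_half_width_offset_closed_form(self):
        # triangles offset by e/2 overlap with score 9/16
        e = 0.08
        val = hs.cosmic(train([1.0]), train([1.0 + e / 2]), e)
        assert val == pytest.approx(9.0 / 16.0, abs=2e-3)

    def test_both_empty_is_one(self):
        assert hs.cosmic(train([]), train([]), 0.05) == 1.0

    @given(st.lists(st.floats(0, 5), max_size=5),
           st.lists(st.floats(0, 5), max_size=5))
    @settings(max_examples=40, deadline=None)
    def test_bounded_and_symmetric(self, a, b):
        s = hs.cosmic(train(a), train(b), 0.1)
        assert 0.0 <= s <= 1.0 + 1e-9
        assert s == pytest.approx(hs.cosmic(train(b), train(a), 0.1), abs=1e-9)

    def test_against_numeric_integration(self, rng):
        for _ in range(20):
            t = np.sort(rng.uniform(0, 3, rng.integers(1, 5)))
            e = np.sort(rng.uniform(0, 3, rng.integers(1, 5)))
            ours = hs.cosmic(train(t), train(e), 0.1)
            ref = triangle_overlap_score(t, e, 0.1)
            assert np.isclose(ours, ref, atol=2e-3)


class TestHyperacuityIndex:
    def test_arithmetic(self):
        assert hs.hyperacuity_index([0.025, -0.025], 10.0) == pytest.approx(4.0)

    def test_zero_errors_guarded(self):
        assert hs.hyperacuity_index([0.0, 0.0], 10.0) == pytest.approx(1e5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hs.hyperacuity_index([], 10.0)

    def test_frame_grid_estimator_converges_to_nyquist_limit(self, rng):
        # an estimator reporting frame onsets for uniform true spike times
        # has mean |error| of half an interval -> index 2
        rate = 10.0
        t = np.sort(rng.uniform(0, 2000, 2000))
        est = np.floor(t * rate) / rate
        _, _, _, errs = hs.match_spikes(train(t), train(est),
                                        index_window(rate))
        assert hs.hyperacuity_index(errs, rate) == pytest.approx(2.0, abs=0.1)


class TestEvaluateAndCv:
    def test_window_rule(self):
        assert hs.matching_window(10.0) == pytest.approx(0.05)
        assert hs.matching_window(20.0) == pytest.approx(0.025)
        assert hs.matching_window(30.0) == pytest.approx(0.05)
        assert hs.matching_window(60.0) == pytest.approx(0.05)

    def test_report_consistency(self, rng):
        t = np.sort(rng.uniform(0, 50, 40))
        e = np.sort(rng.uniform(0, 50, 35))
        rep = hs.evaluate(train(t), train(e), 20.0)
        assert rep.hits + rep.misses == 40
        s, p, f1 = hs.roc_scores(rep.hits, rep.misses, rep.false_positives)
        assert rep.f1 == pytest.approx(f1)

    def test_loocv_produces_one_report_per_cell(self):
        cells = [(hs.CalciumTrace(np.zeros(10) + i, 10.0), train([1.0]))
                 for i in range(3)]

        class Dummy:
            def detect(self, trace):
                return train([1.0])

        reports = hs.loocv(cells, lambda cs, seed: Dummy())
        assert len(reports) == 3
        with pytest.raises(ValueError):
            hs.loocv(cells[:1], lambda cs, seed: Dummy())

    def test_summary_zero_sem_for_constant_metric(self):
        reps = [hs.evaluate(train([1.0]), train([1.0]), 10.0) for _ in range(4)]
        stats = hs.summarize(reps)
        mean, two_sem = stats["f1"]
        assert mean == pytest.approx(1.0)
        assert two_sem == pytest.approx(0.0)
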