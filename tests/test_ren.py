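"""Relative entropy: estimator, all-pairs sweep, grand averages, features."""

import numpy as np
import pandas as pd
import pytest

from seizclust.events import events_to_frame, SeizureEvent
from seizclust.ren import (
    DegenerateSeriesError,
    RENConfig,
    amplitude_distribution,
    assemble_features,
    feature_columns,
    grand_average,
    relative_entropy,
    ren_all_pairs,
    shared_edges,
)
from seizclust.preprocess import SegmentTensor

from oracles import ren_bruteforce


class TestAmplitudeDistribution:
    def test_point_mass_lands_in_one_bin(self):
        x = np.zeros(100)
        edges = np.linspace(-1, 1, 11)
        p = amplitude_distribution(x, RENConfig(), edges)
        assert p.max() > 0.999
        assert p.sum() == pytest.approx(1.0)

    def test_matches_direct_tally(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, size=1000)
        edges = np.linspace(0, 1, 11)
        p = amplitude_distribution(x, RENConfig(smoothing_eps=1e-15), edges)
        tally = np.array([
            np.sum((x >= lo) & ((x < hi) if i < 9 else (x <= hi)))
            for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]))
        ])
        np.testing.assert_allclose(p, tally / 1000, atol=1e-12)

    def test_smoothing_makes_every_bin_positive(self):
        p = amplitude_distribution(np.zeros(50), RENConfig(), np.linspace(-1, 1, 11))
        assert (p > 0).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            amplitude_distribution(np.arange(5), RENConfig(n_bins=10),
                                   np.linspace(0, 5, 11))


class TestRelativeEntropy:
    def test_identical_series_give_zero(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert relative_entropy(x, x) == 0.0

    def test_two_bin_closed_form(self):
        # p=(0.5,0.5) vs q=(0.9,0.1): KL(p||q)=0.5108, KL(q||p)=0.3680 nats
        x = np.array([0.25] * 500 + [0.75] * 500)
        y = np.array([0.25] * 900 + [0.75] * 100)
        cfg = RENConfig(n_bins=2, smoothing_eps=1e-12)
        assert relative_entropy(x, y, cfg) == pytest.approx(0.5108, abs=1e-3)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(800)
        y = rng.standard_normal(800) * 2
        assert relative_entropy(x, y) == relative_entropy(y, x)

    def test_scaled_gaussian_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1000)
        y = 3 * rng.standard_normal(1000)
        assert relative_entropy(x, y) == pytest.approx(
            ren_bruteforce(x, y), abs=1e-12
        )

    def test_shape_difference_detected_after_normalization(self):
        # same mean/variance, different tail weight
        rng = np.random.default_rng(2)
        light = rng.uniform(-np.sqrt(3), np.sqrt(3), 2000)
        heavy = rng.standard_t(df=3, size=2000)
        heavy = (heavy - heavy.mean()) / heavy.std()
        assert relative_entropy(light, heavy) > 0.05

    def test_constant_series_escalates(self):
        with pytest.raises(DegenerateSeriesError):
            relative_entropy(np.zeros(100), np.zeros(100))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            relative_entropy(np.zeros(10), np.zeros(11))


class TestRenAllPairs:
    def test_12_channels_give_66_pairs(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2, 12, 1, 1000))
        seg = SegmentTensor(0, "ictal", data, 400.0, ("beta",))
        res = ren_all_pairs(seg)
        assert len(res.pairs) == 66
        assert res.values.shape == (2, 66, 1)

    def test_identical_channels_give_zero(self):
        rng = np.random.default_rng(1)
        row = rng.standard_normal(1000)
        data = np.tile(row, (1, 4, 1, 1)).reshape(1, 4, 1, 1000)
        seg = SegmentTensor(0, "ictal", data, 400.0, ("beta",))
        res = ren_all_pairs(seg)
        np.testing.assert_allclose(res.values, 0.0, atol=1e-15)

    def test_matches_bruteforce_on_random_pairs(self, small_segment_tensor):
        res = ren_all_pairs(small_segment_tensor)
        rng = np.random.default_rng(9)
        for _ in range(100):
            si = rng.integers(small_segment_tensor.n_segments)
            pi = rng.integers(len(res.pairs))
            bi = rng.integers(2)
            a, b = res.pairs[pi]
            expected = ren_bruteforce(
                small_segment_tensor.data[si, a, bi],
                small_segment_tensor.data[si, b, bi],
            )
            assert res.values[si, pi, bi] == pytest.approx(expected, abs=1e-12)

    def test_values_nonnegative_and_finite(self, small_segment_tensor):
        res = ren_all_pairs(small_segment_tensor)
        assert (res.values >= 0).all()
        assert np.isfinite(res.values).all()

    def test_invalid_segments_skipped(self, small_segment_tensor):
        seg = small_segment_tensor
        seg2 = SegmentTensor(
            seg.seizure_index, seg.period, seg.data, seg.fs, seg.band_names,
            valid=np.array([True, False, True, False]),
        )
        res = ren_all_pairs(seg2)
        assert np.isnan(res.values[1]).all() and np.isnan(res.values[3]).all()
        assert np.isfinite(res.values[0]).all()


class TestGrandAverageAndFeatures:
    def test_constant_values_average_to_constant(self, small_segment_tensor):
        res = ren_all_pairs(small_segment_tensor)
        res.values[:] = 0.37
        ga = grand_average(res)
        assert ga == {"beta": pytest.approx(0.37), "gamma": pytest.approx(0.37)}

    def test_toy_mean(self, small_segment_tensor):
        res = ren_all_pairs(small_segment_tensor)
        res.values[:] = np.nan
        res.values[0, 0, 0] = 1.0
        res.values[0, 1, 0] = 2.0
        res.values[1, 0, 0] = 3.0
        res.values[1, 1, 0] = 4.0
        assert grand_average(res) == {"beta": pytest.approx(2.5)}

    def test_feature_row_has_10_columns(self):
        bands = ("delta", "theta", "alpha", "beta", "gamma")
        assert len(feature_columns(bands)) == 10
        per_seizure = {
            0: {
                "near_seizure": {b: 0.1 for b in bands},
                "ictal": {b: 0.2 for b in bands},
            }
        }
        ann = events_to_frame([SeizureEvent("p0", 100.0, 130.0)])
        labels = pd.DataFrame(
            {"seizure_index": [0], "category": ["isolated"],
             "is_cluster_first": [False], "cluster_id": [None]}
        )
        df = assemble_features(per_seizure, ann, labels)
        assert len(df) == 1
        assert [c for c in df.columns if c.startswith("ga_ren_")] == \
            feature_columns(bands)

    def test_incomplete_rows_dropped(self):
        bands = ("beta",)
        per_seizure = {
            0: {"near_seizure": {"beta": 0.1}},  # ictal missing
            1: {"near_seizure": {"beta": 0.1}, "ictal": {"beta": 0.2}},
        }
        events = [SeizureEvent("p0", 100.0, 101.0), SeizureEvent("p0", 90000.0, 90039.0)]
        labels = pd.DataFrame(
            {"seizure_index": [0, 1], "category": ["isolated", "isolated"],
             "is_cluster_first": [False, False], "cluster_id": [None, None]}
        )
        df = assemble_features(per_seizure, events_to_frame(events), labels)
        assert df.seizure_index.tolist() == [1]


def test_shared_edges_span_pooled_range():
    x = np.array([-2.0, 0.0, 1.0])
    y = np.array([-1.0, 3.0])
    edges = shared_edges(x, y, 10)
    assert edges[0] == -2.0 and edges[-1] == 3.0 and len(edges) == 11
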