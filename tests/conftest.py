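"""Shared fixtures: small synthetic cohorts reused across the suite.

The simulation-backed fixtures are session-scoped because generating
signals and sweeping REN over all channel pairs is the expensive part of
the pipeline; every test that needs a realistic feature table shares them.
Problem sizes (60 s near-seizure windows, 100-300 seizures) are chosen so
the whole suite runs in minutes while keeping group sizes large enough for
the statistical checks.
"""

from __future__ import annotations

import numpy as np
import pytest

import seizclust as sz
from seizclust.config import PipelineConfig, PreprocessConfig
from seizclust.pipeline import compute_patient_features
from seizclust.taxonomy import label_seizures, labels_to_frame

#: "Large" near-seizure effect: spread ratio 3x, fixed by pre-build
#: Monte-Carlo over replicate seeds.
LARGE_EFFECT = dict(effect_near=2.0, effect_ictal=1.0)


def make_features(sim: sz.SimConfig, near_window_s: float = 60.0):
    """Run schedule -> signals -> segments -> REN -> feature table."""
    events, truth = sz.simulate_schedule(sim)
    rec, _ = sz.simulate_signals(sim, events, truth)
    cfg = PipelineConfig(
        sim=sim, preprocess=PreprocessConfig(near_window_s=near_window_s)
    )
    labels = labels_to_frame(label_seizures(events))
    feats = compute_patient_features(rec, events, labels, cfg)
    return feats, events, truth, cfg


@pytest.fixture(scope="session")
def effect_features():
    """One patient with the large cluster/isolated REN effect (~150 seizures)."""
    sim = sz.SimConfig(
        recording_days=170, seed=11, active_window_s=60.0, **LARGE_EFFECT
    )
    feats, events, truth, cfg = make_features(sim)
    return feats


@pytest.fixture(scope="session")
def small_segment_tensor():
    """A small normalized SegmentTensor (6 channels) for REN unit tests."""
    rng = np.random.default_rng(7)
    n_seg, n_ch, n_band, n_samp = 4, 6, 2, 1000
    data = rng.standard_normal((n_seg, n_ch, n_band, n_samp))
    data -= data.mean(axis=3, keepdims=True)
    data /= data.std(axis=3, keepdims=True)
    return sz.SegmentTensor(0, "ictal", data, 400.0, ("beta", "gamma"))
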