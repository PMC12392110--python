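"""Shared fixtures: small synthetic recordings and the heavyweight
session-scoped artifacts (the 12-recording control cohort spectra and the
trained detector) reused across spectral and accuracy tests."""

from __future__ import annotations

import numpy as np
import pytest

from sleseg.detector import SLEDetector
from sleseg.io import LabelSeries, Recording, downsample
from sleseg.postprocess import events_to_labels
from sleseg.spectral import binned_psd
from sleseg.synth import SimRecordingConfig, simulate_recording


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def short_recording():
    """A 60-s default-parameter simulated recording with ground truth."""
    cfg = SimRecordingConfig(duration_s=60.0, seed=7)
    return simulate_recording(cfg, recording_id="short", meta={"treatment": "ctrl"})


@pytest.fixture(scope="session")
def control_psds():
    """Normalized 0.2-Hz-binned PSDs of 12 simulated 40-min control
    recordings (default generator configuration, seeds 1..12)."""
    psds = []
    for seed in range(1, 13):
        rec, _ = simulate_recording(SimRecordingConfig(seed=seed), recording_id=f"c{seed}")
        psds.append(binned_psd(rec))
    return psds


def make_labeled_cohort(n_recordings: int, duration_s: float, seed0: int, rate: float = 125.0):
    """Simulate recordings, downsample to the label rate and derive truth labels."""
    recs, labels, truths = [], [], []
    for i in range(n_recordings):
        cfg = SimRecordingConfig(duration_s=duration_s, seed=seed0 + i)
        rec, truth = simulate_recording(cfg, recording_id=f"r{i}", meta={"treatment": "ctrl"})
        rec_l = downsample(rec, rate)
        lab = events_to_labels(truth.at_rate(rate), rec_l.n_samples)
        recs.append(rec_l)
        labels.append(LabelSeries(lab.labels, rate))
        truths.append(truth)
    return recs, labels, truths


@pytest.fixture(scope="session")
def trained_detector():
    """Detector trained on ~60 min of synthetic signal (desk-scale config:
    8 blocks, 16 channels, 12 epochs), validated on two held-out recordings."""
    recs, labels, _ = make_labeled_cohort(8, 600.0, seed0=100)
    det = SLEDetector(
        n_blocks=8,
        channels=16,
        epochs=12,
        batch_size=8,
        val_fraction=0.25,
        random_state=0,
    )
    det.fit(recs, labels)
    return det, recs, labels
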