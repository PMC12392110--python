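"""Augmentation, balanced splitting, training loop behaviour and
whole-recording prediction."""

import numpy as np
import pytest
from scipy.signal import periodogram

from sleseg.detector import (
    AugmentationSpec,
    SLEDetector,
    SplitPlan,
    TrainConfig,
    augment,
    duplicate_with_inversion,
    predict,
    split_train_val,
    train,
)
from sleseg.io import LabelSeries, Recording, SegmentBatch
from sleseg.nn import DetectorConfig, WaveNet1D


def make_batch(n=8, length=3750, rate=125.0, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n, length))
    targ = (rng.random((n, length)) < 0.3).astype(np.uint8)
    prov = [(f"r{i % 3}", i * length) for i in range(n)]
    return SegmentBatch(data, targ, rate, prov)


class TestInversionDuplication:
    def test_doubles_and_negates(self):
        b = make_batch(n=5)
        out = duplicate_with_inversion(b)
        assert len(out) == 10
        np.testing.assert_array_equal(out.data[5:], -b.data)
        np.testing.assert_array_equal(out.targets[5:], b.targets)

    def test_empty_batch(self):
        b = SegmentBatch(np.empty((0, 10)), np.empty((0, 10), dtype=np.uint8), 125.0, [])
        assert len(duplicate_with_inversion(b)) == 0

    def test_composition_quadruples(self):
        b = make_batch(n=3)
        out = duplicate_with_inversion(duplicate_with_inversion(b))
        assert len(out) == 12
        np.testing.assert_array_equal(out.data[6:], -out.data[:6])


class TestAugmentation:
    def test_exact_quarter_fractions(self):
        b = make_batch(n=1000, length=750)
        out = augment(b, AugmentationSpec(burst_s=5.0), seed=0)
        changed = np.sum(np.any(out.data != b.data, axis=1))
        # three quarters are modified; the unchanged quarter is exactly 250
        assert changed == 750
        np.testing.assert_array_equal(out.targets, b.targets)

    def test_burst_replaces_exactly_5s(self):
        rate = 125.0
        b = SegmentBatch(
            np.zeros((4, 3750)), np.zeros((4, 3750), dtype=np.uint8), rate, [("r", 0)] * 4
        )
        out = augment(b, AugmentationSpec(fractions=(0, 0, 1, 0)), seed=1)
        for row in out.data:
            assert np.sum(row != 0) == 625  # 5 s x 125 Hz

    def test_hum_component_is_50hz(self):
        rate = 125.0
        b = SegmentBatch(
            np.zeros((2, 3750)), np.zeros((2, 3750), dtype=np.uint8), rate, [("r", 0)] * 2
        )
        out = augment(b, AugmentationSpec(fractions=(0, 1, 0, 0), hum_noise_sd=0.0), seed=2)
        f, p = periodogram(out.data[0], fs=rate)
        assert f[np.argmax(p)] == pytest.approx(50.0, abs=0.2)

    def test_segment_shorter_than_burst_rejected(self):
        b = make_batch(n=4, length=100)
        with pytest.raises(ValueError):
            augment(b, AugmentationSpec(burst_s=5.0), seed=0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            AugmentationSpec(fractions=(0.5, 0.5, 0.5, 0.0))


def make_labeled(rec_id, sle_seconds, treated, rate=125.0, dur_s=60.0):
    n = int(dur_s * rate)
    lab = np.zeros(n, dtype=np.uint8)
    lab[: int(sle_seconds * rate)] = 1
    rec = Recording(
        np.random.default_rng(hash(rec_id) % 2**31).standard_normal(n),
        rate,
        rec_id,
        {"treatment": "CNB120" if treated else "ctrl"},
    )
    return rec, LabelSeries(lab, rate)


class TestSplit:
    def test_val_count_with_equal_loads(self):
        pairs = [make_labeled(f"r{i}", 10.0, False) for i in range(10)]
        plan = split_train_val(pairs, val_fraction=0.2)
        n_val = sum(1 for v in plan.assignment.values() if v == "validation")
        assert n_val == 2
        assert set(plan.assignment) == {f"r{i}" for i in range(10)}

    def test_treated_share_balanced(self):
        pairs = [make_labeled(f"t{i}", 5.0 + i, True) for i in range(5)]
        pairs += [make_labeled(f"u{i}", 5.0 + i, False) for i in range(5)]
        plan = split_train_val(pairs, val_fraction=0.4)
        assert abs(plan.treated_share_train - 0.5) <= 0.10
        assert abs(plan.treated_share_val - 0.5) <= 0.10
        # SLE-duration share of validation near its target
        assert abs(plan.sle_duration_share_val - 0.4) <= 0.10

    def test_single_recording_rejected(self):
        with pytest.raises(ValueError):
            split_train_val([make_labeled("only", 5.0, False)])

    def test_recording_exclusive_and_deterministic(self):
        pairs = [make_labeled(f"r{i}", 3.0 * i + 1, i % 2 == 0) for i in range(8)]
        p1 = split_train_val(pairs, 0.25)
        p2 = split_train_val(pairs, 0.25)
        assert p1.assignment == p2.assignment
        assert set(p1.assignment.values()) == {"train", "validation"}


def tiny_training_setup(n_recs=3, dur_s=8.0, seed=0):
    """Trivially separable data: big negative deflections mark events."""
    rate = 125.0
    cfg = DetectorConfig(input_rate_hz=rate, segment_s=4.0, n_blocks=3, channels=4, dilations=(1, 2, 4))
    rng = np.random.default_rng(seed)
    recs, labels = [], []
    for i in range(n_recs):
        n = int(dur_s * rate)
        x = 0.1 * rng.standard_normal(n)
        lab = np.zeros(n, dtype=np.uint8)
        for start in range(100, n - 120, 250):
            x[start : start + 60] -= 3.0
            lab[start : start + 60] = 1
        recs.append(Recording(x, rate, f"r{i}"))
        labels.append(LabelSeries(lab, rate))
    segs = []
    targs = []
    L = int(4.0 * rate)
    for rec, lab in zip(recs[:-1], labels[:-1]):  # hold out last recording
        k = rec.n_samples // L
        segs.append(rec.samples[: k * L].reshape(k, L))
        targs.append(lab.labels[: k * L].reshape(k, L))
    batch = SegmentBatch(np.concatenate(segs), np.concatenate(targs), rate, [("r", 0)] * sum(s.shape[0] for s in segs))
    return cfg, batch, [(recs[-1], labels[-1])]


class TestTrainLoop:
    def test_single_epoch_history(self):
        cfg, batch, val = tiny_training_setup()
        model = WaveNet1D(cfg, seed=0)
        hist = train(model, batch, val, TrainConfig(epochs=1, batch_size=4, seed=0))
        assert len(hist) == 1
        assert set(hist.columns) >= {"epoch", "loss", "raw_val_accuracy", "corrected_val_accuracy", "learning_rate"}

    def test_plateau_divides_learning_rate_by_10(self):
        # saturating problem: accuracy stops improving, so the schedule must fire
        cfg, batch, val = tiny_training_setup()
        model = WaveNet1D(cfg, seed=0)
        hist = train(model, batch, val, TrainConfig(epochs=12, initial_learning_rate=1e-2, batch_size=4, seed=0))
        lrs = hist["learning_rate"].to_numpy()
        assert lrs[0] == pytest.approx(1e-2)
        assert lrs[-1] < lrs[0]
        drops = lrs[:-1] / lrs[1:]
        assert np.all(np.isin(np.round(drops[drops > 1.5]), [10]))

    def test_empty_training_rejected(self):
        cfg, batch, val = tiny_training_setup()
        empty = SegmentBatch(np.empty((0, 500)), np.empty((0, 500), dtype=np.uint8), 125.0, [])
        with pytest.raises(ValueError):
            train(WaveNet1D(cfg, seed=0), empty, val, TrainConfig(epochs=1))


class TestPredict:
    def test_wrong_rate_rejected(self):
        cfg, _, val = tiny_training_setup()
        model = WaveNet1D(cfg, seed=0)
        rec2000 = Recording(np.zeros(4000) + np.arange(4000) % 7, 2000.0, "raw")
        with pytest.raises(ValueError, match="rate"):
            predict(model, rec2000)

    def test_length_and_determinism(self):
        cfg, _, val = tiny_training_setup()
        model = WaveNet1D(cfg, seed=0)
        rec, _ = val[0]
        p1 = predict(model, rec)
        p2 = predict(model, rec)
        assert p1.shape == (rec.n_samples,)
        np.testing.assert_array_equal(p1, p2)

    def test_partial_trailing_window_handled(self):
        cfg, _, _ = tiny_training_setup()
        model = WaveNet1D(cfg, seed=0)
        n = int(4.0 * 125) * 2 + 100  # two full segments plus a remainder
        rec = Recording(np.sin(np.arange(n) / 5.0), 125.0, "partial")
        assert predict(model, rec).shape == (n,)


class TestEstimatorContract:
    def test_get_set_params_clone(self):
        from sklearn.base import clone

        det = SLEDetector(n_blocks=4, channels=8, epochs=2)
        params = det.get_params()
        assert params["channels"] == 8
        det2 = clone(det)
        assert det2.get_params() == params
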