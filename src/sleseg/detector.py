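"""Training and inference for the per-sample SLE classifier.

Covers the full supervised workflow around :class:`sleseg.nn.WaveNet1D`:

* recording-exclusive train/validation splitting, balanced on the total SLE
  duration and on the share of treated recordings,
* dataset duplication with sign inversion (LFP polarity is arbitrary),
* four-way noise augmentation of the training quarters (unchanged / weak
  50-Hz hum plus Gaussian noise / 5-s Gaussian-burst replacement / pointwise
  Gaussian replacement), which corrupts inputs but never targets,
* the training loop: binary cross-entropy, Adam, learning rate divided by 10
  when the algorithmically corrected validation accuracy fails to improve
  for more than ``plateau_patience`` epochs, best-epoch weights retained,
* sequential whole-recording prediction with per-segment standardization
  identical to training.

The public surface is the sklearn-style :class:`SLEDetector` estimator; the
module-level functions are the individual stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import LabelSeries, Recording, SegmentBatch, segment, standardize_segment
from .nn import Adam, DetectorConfig, WaveNet1D, bce_with_logits
from .postprocess import PostprocessConfig, correct, corrected_accuracy

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "AugmentationSpec",
    "SplitPlan",
    "build_model",
    "duplicate_with_inversion",
    "augment",
    "split_train_val",
    "train",
    "predict",
    "SLEDetector",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    initial_learning_rate: float = 1e-3
    plateau_patience_epochs: int = 2
    lr_decay_factor: float = 10.0
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_decay_factor <= 1:
            raise ValueError("decay factor must be > 1")
        if self.plateau_patience_epochs < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class AugmentationSpec:
    """Quarter assignment of the training data to noise categories.

    Fractions must sum to 1.  Amplitudes are in units of the (standardized)
    segment scale.  The hum is a true 50-Hz tone, representable at the
    125-Hz label rate (Nyquist 62.5 Hz).
    """

    fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    hum_amplitude: float = 0.1
    hum_noise_sd: float = 0.1
    burst_s: float = 5.0
    burst_sd: float = 1.0
    pointwise_fraction: float = 0.1
    pointwise_sd: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")


@dataclass
class SplitPlan:
    """Recording-exclusive assignment plus achieved balance diagnostics."""

    assignment: dict[str, str]  # recording_id -> "train" | "validation"
    sle_duration_share_val: float
    treated_share_train: float
    treated_share_val: float

    def side(self, recording_id: str) -> str:
        return self.assignment[recording_id]


def build_model(config: DetectorConfig, seed: int = 0) -> WaveNet1D:
    """Instantiate the classifier; identical seed gives identical weights."""
    model = WaveNet1D(config, seed=seed)
    logger.info("built model with %d parameters", model.n_parameters)
    return model


def duplicate_with_inversion(batch: SegmentBatch) -> SegmentBatch:
    """Append a sign-inverted copy of every segment; targets unchanged."""
    if len(batch) == 0:
        return batch
    data = np.concatenate([batch.data, -batch.data], axis=0)
    targets = np.concatenate([batch.targets, batch.targets], axis=0)
    prov = batch.provenance + [(rid, start) for rid, start in batch.provenance]
    return SegmentBatch(data, targets, batch.sampling_rate_hz, prov)


def _category_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment; deterministic."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([-(r - b) for r, b in zip(raw, base)], kind="stable")
    for k in range(rem):
        base[order[k]] += 1
    return base


def augment(batch: SegmentBatch, spec: AugmentationSpec = AugmentationSpec(), seed: int = 0) -> SegmentBatch:
    """Apply the four-way noise augmentation to a standardized batch.

    Exactly the configured fractions of segments fall into each category
    (largest-remainder rounding over a seeded permutation); targets are
    never altered.
    """
    n, length = len(batch), batch.segment_length
    burst_n = int(round(spec.burst_s * batch.sampling_rate_hz))
    if spec.fractions[2] > 0 and burst_n > length:
        raise ValueError("segment shorter than the burst replacement length")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    counts = _category_counts(n, spec.fractions)
    data = batch.data.copy()
    t = np.arange(length) / batch.sampling_rate_hz
    start = counts[0]  # category 0: unchanged
    for idx in perm[start : start + counts[1]]:  # 50-Hz hum + Gaussian noise
        phase = rng.uniform(0, 2 * np.pi)
        data[idx] += spec.hum_amplitude * np.sin(2 * np.pi * 50.0 * t + phase)
        data[idx] += rng.normal(0.0, spec.hum_noise_sd, size=length)
    start += counts[1]
    for idx in perm[start : start + counts[2]]:  # contiguous 5-s burst replacement
        pos = int(rng.integers(0, length - burst_n + 1))
        data[idx, pos : pos + burst_n] = rng.normal(0.0, spec.burst_sd, size=burst_n)
    start += counts[2]
    for idx in perm[start : start + counts[3]]:  # pointwise Gaussian replacement
        mask = rng.random(length) < spec.pointwise_fraction
        data[idx, mask] = rng.normal(0.0, spec.pointwise_sd, size=int(mask.sum()))
    return SegmentBatch(data, batch.targets.copy(), batch.sampling_rate_hz, list(batch.provenance))


def _is_treated(rec: Recording) -> bool:
    return rec.meta.get("treatment", "ctrl") not in ("", "ctrl", "control")


def split_train_val(
    recordings: list[tuple[Recording, LabelSeries]],
    val_fraction: float = 0.2,
) -> SplitPlan:
    """Greedy recording-exclusive split balancing SLE time and treated share.

    Recordings are stratified by treatment status; within each stratum they
    are ordered by total SLE duration (descending) and assigned greedily to
    the side whose accumulated SLE duration is furthest below its target
    share.  Deterministic by construction.
    """
    if len(recordings) < 2:
        raise ValueError("need at least two recordings to split")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must lie in (0, 1)")
    info = []
    for rec, lab in recordings:
        sle_s = float(lab.labels.sum() / lab.sampling_rate_hz)
        info.append((rec.recording_id, sle_s, _is_treated(rec)))
    assignment: dict[str, str] = {}
    for treated in (True, False):
        stratum = sorted([x for x in info if x[2] == treated], key=lambda x: (-x[1], x[0]))
        if not stratum:
            continue
        n_val = int(round(val_fraction * len(stratum)))
        total = sum(x[1] for x in stratum) or 1.0
        acc = {"validation": 0.0, "train": 0.0}
        quota = {"validation": n_val, "train": len(stratum) - n_val}
        target = {"validation": val_fraction, "train": 1.0 - val_fraction}
        for rid, dur, _ in stratum:
            open_sides = [s for s in ("validation", "train") if quota[s] > 0]
            side = max(open_sides, key=lambda s: target[s] - acc[s] / total)
            assignment[rid] = side
            acc[side] += dur
            quota[side] -= 1
    # guarantee both sides non-empty
    sides = set(assignment.values())
    if "validation" not in sides:
        assignment[min(info, key=lambda x: x[1])[0]] = "validation"
    if "train" not in set(assignment.values()):
        assignment[max(info, key=lambda x: x[1])[0]] = "train"
    total_sle = sum(x[1] for x in info) or 1.0
    val_sle = sum(x[1] for x in info if assignment[x[0]] == "validation")
    n_tr = sum(1 for x in info if assignment[x[0]] == "train")
    n_va = len(info) - n_tr
    tr_treated = sum(1 for x in info if assignment[x[0]] == "train" and x[2])
    va_treated = sum(1 for x in info if assignment[x[0]] == "validation" and x[2])
    return SplitPlan(
        assignment,
        sle_duration_share_val=val_sle / total_sle,
        treated_share_train=tr_treated / n_tr if n_tr else 0.0,
        treated_share_val=va_treated / n_va if n_va else 0.0,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _standardized_batch(batch: SegmentBatch) -> SegmentBatch:
    return SegmentBatch(
        standardize_segment(batch.data),
        batch.targets,
        batch.sampling_rate_hz,
        list(batch.provenance),
    )


def train(
    model: WaveNet1D,
    train_batch: SegmentBatch,
    val_recordings: list[tuple[Recording, LabelSeries]],
    config: TrainConfig = TrainConfig(),
    postprocess: PostprocessConfig = PostprocessConfig(),
) -> pd.DataFrame:
    """Train in place; returns the per-epoch history.

    History columns: epoch, loss, raw_val_accuracy, corrected_val_accuracy,
    learning_rate.  "Improvement" for the plateau rule means any increase of
    the corrected validation accuracy over the best seen so far; after more
    than ``plateau_patience_epochs`` epochs without improvement the learning
    rate is divided by ``lr_decay_factor``.  The best epoch's weights are
    restored at the end.
    """
    if len(train_batch) == 0 or len(val_recordings) == 0:
        raise ValueError("training and validation data must be non-empty")
    rng = np.random.default_rng(config.seed)
    x = train_batch.data.astype(np.float32)
    y = train_batch.targets.astype(np.float32)
    opt = Adam(model.params, lr=config.initial_learning_rate)
    best_acc = -1.0
    best_params: dict[str, np.ndarray] | None = None
    stall = 0
    rows = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_batch))
        losses = []
        for i0 in range(0, len(order), config.batch_size):
            idx = order[i0 : i0 + config.batch_size]
            logits, cache = model.forward(x[idx], want_cache=True)
            loss, dz = bce_with_logits(logits, y[idx])
            grads = model.backward(dz, cache)
            opt.step(grads)
            losses.append(loss)
        raw_acc, corr_acc = _validation_accuracies(model, val_recordings, postprocess)
        rows.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "raw_val_accuracy": raw_acc,
                "corrected_val_accuracy": corr_acc,
                "learning_rate": opt.lr,
            }
        )
        if corr_acc > best_acc:
            best_acc = corr_acc
            best_params = {k: v.copy() for k, v in model.params.items()}
            stall = 0
        else:
            stall += 1
            if stall > config.plateau_patience_epochs:
                opt.lr /= config.lr_decay_factor
                stall = 0
                logger.info("epoch %d: plateau, learning rate now %.2e", epoch, opt.lr)
    if best_params is not None:
        model.params.update(best_params)
    return pd.DataFrame(rows)


def _validation_accuracies(
    model: WaveNet1D,
    val_recordings: list[tuple[Recording, LabelSeries]],
    postprocess: PostprocessConfig,
) -> tuple[float, float]:
    raw_hits = raw_n = 0
    corr_hits = corr_n = 0
    for rec, lab in val_recordings:
        probs = predict(model, rec)
        raw_hits += int(np.sum((probs >= 0.5) == (lab.labels == 1)))
        raw_n += len(lab)
        events = correct(probs, rec, postprocess)
        corr = corrected_accuracy(events, lab)
        corr_hits += corr * len(lab)
        corr_n += len(lab)
    return raw_hits / raw_n, corr_hits / corr_n


def predict(model: WaveNet1D, rec: Recording, batch_size: int = 16) -> np.ndarray:
    """Per-sample SLE probabilities for a whole label-rate recording.

    Segments are standardized exactly as during training and processed in
    order; a trailing partial window is zero-padded and truncated back.
    """
    cfg = model.config
    if abs(rec.sampling_rate_hz - cfg.input_rate_hz) > 1e-9:
        raise ValueError(
            f"recording rate {rec.sampling_rate_hz} Hz differs from model input rate "
            f"{cfg.input_rate_hz} Hz; downsample first"
        )
    L = cfg.segment_samples
    n = rec.n_samples
    n_full = int(np.ceil(n / L))
    padded = np.zeros(n_full * L, dtype=np.float64)
    padded[:n] = rec.samples
    segs = padded.reshape(n_full, L)
    segs = standardize_segment(segs)
    probs = np.empty((n_full, L), dtype=np.float32)
    for i0 in range(0, n_full, batch_size):
        probs[i0 : i0 + batch_size] = model.predict_proba(segs[i0 : i0 + batch_size].astype(np.float32))
    return probs.reshape(-1)[:n].astype(np.float64)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------


class SLEDetector(BaseEstimator):
    """Per-sample SLE classifier with the sklearn estimator contract.

    ``fit(X, y)`` takes a list of label-rate (125-Hz) :class:`Recording`
    objects and a matching list of :class:`LabelSeries`.  Recordings are
    split recording-exclusively, segmented into 30-s windows, standardized,
    duplicated with sign inversion and noise-augmented, then the network is
    trained with plateau learning-rate decay.  ``predict(recording)``
    returns per-sample probabilities, ``predict_events`` the corrected
    event list.

    Fitted attributes: ``model_``, ``history_``, ``split_plan_``,
    ``n_parameters_``.
    """

    def __init__(
        self,
        n_blocks: int = 10,
        channels: int = 32,
        dilations: tuple[int, ...] | None = None,
        padding_mode: str = "symmetric",
        input_rate_hz: float = 125.0,
        segment_s: float = 30.0,
        epochs: int = 100,
        initial_learning_rate: float = 1e-3,
        plateau_patience_epochs: int = 2,
        lr_decay_factor: float = 10.0,
        batch_size: int = 32,
        val_fraction: float = 0.2,
        augment_noise: bool = True,
        binarize_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.n_blocks = n_blocks
        self.channels = channels
        self.dilations = dilations
        self.padding_mode = padding_mode
        self.input_rate_hz = input_rate_hz
        self.segment_s = segment_s
        self.epochs = epochs
        self.initial_learning_rate = initial_learning_rate
        self.plateau_patience_epochs = plateau_patience_epochs
        self.lr_decay_factor = lr_decay_factor
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.augment_noise = augment_noise
        self.binarize_threshold = binarize_threshold
        self.random_state = random_state

    # -- config plumbing ---------------------------------------------------

    @property
    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(
            input_rate_hz=self.input_rate_hz,
            segment_s=self.segment_s,
            n_blocks=self.n_blocks,
            channels=self.channels,
            dilations=self.dilations,
            padding_mode=self.padding_mode,
        )

    @property
    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            initial_learning_rate=self.initial_learning_rate,
            plateau_patience_epochs=self.plateau_patience_epochs,
            lr_decay_factor=self.lr_decay_factor,
            batch_size=self.batch_size,
            seed=self.random_state,
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X: list[Recording], y: list[LabelSeries]) -> "SLEDetector":
        if len(X) != len(y):
            raise ValueError("one label series per recording required")
        pairs = list(zip(X, y))
        plan = split_train_val(pairs, self.val_fraction)
        train_pairs = [p for p in pairs if plan.side(p[0].recording_id) == "train"]
        val_pairs = [p for p in pairs if plan.side(p[0].recording_id) == "validation"]
        batches = [segment(rec, lab, self.segment_s) for rec, lab in train_pairs]
        data = np.concatenate([b.data for b in batches if len(b)], axis=0)
        targ = np.concatenate([b.targets for b in batches if len(b)], axis=0)
        prov = [pv for b in batches for pv in b.provenance]
        batch = SegmentBatch(data, targ, self.input_rate_hz, prov)
        batch = _standardized_batch(batch)
        batch = duplicate_with_inversion(batch)
        if self.augment_noise:
            batch = augment(batch, AugmentationSpec(), seed=self.random_state)
        self.model_ = build_model(self.detector_config, seed=self.random_state)
        self.n_parameters_ = self.model_.n_parameters
        self.history_ = train(
            self.model_,
            batch,
            val_pairs,
            self.train_config,
            PostprocessConfig(binarize_threshold=self.binarize_threshold),
        )
        self.split_plan_ = plan
        return self

    def predict(self, recording: Recording) -> np.ndarray:
        """Per-sample SLE probabilities."""
        return predict(self.model_, recording)

    def predict_events(self, recording: Recording, config: PostprocessConfig | None = None):
        cfg = config or PostprocessConfig(binarize_threshold=self.binarize_threshold)
        return correct(self.predict(recording), recording, cfg)

    def score(self, X: list[Recording], y: list[LabelSeries]) -> float:
        """Mean corrected per-sample validation accuracy over recordings."""
        _, corr = _validation_accuracies(
            self.model_, list(zip(X, y)), PostprocessConfig(binarize_threshold=self.binarize_threshold)
        )
        return corr
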