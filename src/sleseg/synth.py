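"""Synthetic LFP generator with ground-truth seizure-like events.

Emulates disinhibition-model slice recordings: band-limited baseline noise,
seizure-like events (SLEs) as near-rhythmic trains of similar-morphology
spikes (~10 Hz within events), isolated interictal spikes between events, and
optional 50-Hz mains contamination.  Every generated event respects the
operational SLE definition used for manual labeling: duration >= 0.2 s and
inter-event separation >= ``min_gap_s`` (default 0.1 s).

Event onsets follow a renewal process: each inter-event gap is
``min_gap_s + Exponential(theta)`` with ``theta`` chosen so that the mean
cycle length (gap + event duration) matches the configured event rate.
Treatment effects are expressed as multiplicative factors on event duration,
intra-event spike frequency and event rate, which is how anticonvulsant
effects on these metrics are summarized.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawn keys, so cohorts are reproducible
regardless of generation order, and matched (animal, slice) positions share
random streams across groups (common random numbers): a treatment effect of
(1, 1, 1) reproduces the control recordings bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.stats import norm

from .io import Event, EventList, Recording

__all__ = [
    "SimRecordingConfig",
    "TreatmentEffect",
    "SimCohortConfig",
    "SimulatedSlice",
    "waveform_kernel",
    "simulate_recording",
    "simulate_cohort",
    "expected_event_count",
]

MIN_SLE_DURATION_S = 0.2  # operational definition: events last at least 0.2 s


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative treatment effect on the three generative knobs.

    The identity element (1, 1, 1) leaves the generative distribution
    unchanged.
    """

    duration_multiplier: float = 1.0
    spike_freq_multiplier: float = 1.0
    rate_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.duration_multiplier, self.spike_freq_multiplier, self.rate_multiplier):
            if not v > 0:
                raise ConfigurationError("treatment multipliers must be > 0")


@dataclass(frozen=True)
class SimRecordingConfig:
    """Parameters of one simulated recording.

    Defaults mirror the experimental conditions: a 40-min analysis window
    sampled at 2,000 Hz, ~12 events/min with ~10-Hz spiking inside events,
    acquisition low-pass at 30 Hz, and occasional interictal spikes.
    Amplitudes are in arbitrary signal units relative to the baseline noise
    standard deviation.
    """

    duration_s: float = 2400.0
    sampling_rate_hz: float = 2000.0
    sle_rate_per_min: float = 12.0
    sle_duration_mean_s: float = 2.0
    sle_duration_cv: float = 0.5
    intra_sle_spike_hz: float = 10.0
    spike_amplitude: float = 8.0
    spike_amplitude_cv: float = 0.2
    spike_width_s: float = 0.02
    isi_cv: float = 0.05
    min_gap_s: float = 0.1
    baseline_noise_sd: float = 1.0
    lowpass_cutoff_hz: float = 30.0
    interictal_rate_per_min: float = 2.0
    interictal_amplitude: float = 6.0
    interictal_width_s: float = 0.03
    hum_50hz_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be > 0")
        if self.sle_rate_per_min < 0:
            raise ConfigurationError("sle_rate_per_min must be >= 0")
        if self.min_gap_s < 0.1:
            raise ConfigurationError("min_gap_s must be >= 0.1 (event separation definition)")
        if self.sle_duration_mean_s <= 0 or self.sle_duration_cv < 0:
            raise ConfigurationError("invalid duration distribution parameters")
        if self.intra_sle_spike_hz <= 0:
            raise ConfigurationError("intra_sle_spike_hz must be > 0")
        if self.spike_width_s <= 0 or self.interictal_width_s <= 0:
            raise ConfigurationError("kernel widths must be > 0")
        if self.baseline_noise_sd < 0 or self.interictal_rate_per_min < 0:
            raise ConfigurationError("noise/interictal parameters must be >= 0")

    def with_effect(self, eff: TreatmentEffect) -> "SimRecordingConfig":
        return replace(
            self,
            sle_duration_mean_s=self.sle_duration_mean_s * eff.duration_multiplier,
            intra_sle_spike_hz=self.intra_sle_spike_hz * eff.spike_freq_multiplier,
            sle_rate_per_min=self.sle_rate_per_min * eff.rate_multiplier,
        )


@dataclass(frozen=True)
class SimCohortConfig:
    """A cohort: groups x animals x slices, each slice one recording.

    With ``paired_seeds`` (default), matched (animal, slice) positions share
    their random stream across groups, so an identity treatment effect
    reproduces the control recordings exactly and effect-recovery contrasts
    are variance-reduced.  Set it to False for independent groups (e.g. null
    simulations of the statistical layer).
    """

    groups: tuple[tuple[str, TreatmentEffect], ...]
    animals_per_group: int = 3
    slices_per_animal: tuple[int, int] = (2, 6)
    base: SimRecordingConfig = field(default_factory=SimRecordingConfig)
    seed: int = 0
    paired_seeds: bool = True

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ConfigurationError("at least one group required")
        lo, hi = self.slices_per_animal
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid slices_per_animal range")
        if self.animals_per_group < 1:
            raise ConfigurationError("animals_per_group must be >= 1")


@dataclass
class SimulatedSlice:
    """One simulated recording with its ground truth and cohort coordinates."""

    recording: Recording
    truth: EventList
    group: str
    animal_id: str
    slice_id: str


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def waveform_kernel(
    kind: str,
    amplitude: float,
    width_s: float,
    sampling_rate_hz: float,
) -> np.ndarray:
    """Zero-baseline single-trough snippet used to stamp spikes.

    A negative Gaussian of scale ``width_s`` truncated at +-4 widths; the
    trough is the unique strict minimum at the center sample.  Doubling
    ``width_s`` yields a time-stretched copy with the same trough depth.
    ``kind`` selects the semantic role (``"spike"`` inside events,
    ``"interictal"`` between events); both share the same parametric shape.
    """
    if kind not in ("spike", "interictal"):
        raise ConfigurationError(f"unknown kernel kind {kind!r}")
    if width_s <= 0 or sampling_rate_hz <= 0:
        raise ConfigurationError("kernel width and rate must be > 0")
    half = max(1, int(round(4.0 * width_s * sampling_rate_hz)))
    t = np.arange(-half, half + 1) / sampling_rate_hz
    return -amplitude * np.exp(-0.5 * (t / width_s) ** 2)


# ---------------------------------------------------------------------------
# event process
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and coefficient of variation."""
    if cv == 0:
        return np.log(mean), 0.0
    sigma2 = np.log(1.0 + cv**2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _truncated_lognormal_mean(mean: float, cv: float, lower: float) -> float:
    """Mean of a lognormal(mean, cv) conditioned on exceeding ``lower``."""
    mu, sig = _lognormal_params(mean, cv)
    if sig == 0:
        return max(mean, lower)
    tail = norm.sf((np.log(lower) - mu) / sig)
    partial = mean * norm.sf((np.log(lower) - mu - sig**2) / sig)
    return partial / tail


def _gap_theta(cfg: SimRecordingConfig) -> float:
    """Exponential scale of the gap process matching the configured rate."""
    rate_s = cfg.sle_rate_per_min / 60.0
    mean_dur = _truncated_lognormal_mean(cfg.sle_duration_mean_s, cfg.sle_duration_cv, MIN_SLE_DURATION_S)
    theta = 1.0 / rate_s - mean_dur - cfg.min_gap_s
    if theta <= 0:
        raise ConfigurationError(
            "configured SLE rate infeasible given mean duration and minimum gap"
        )
    return theta


def expected_event_count(cfg: SimRecordingConfig) -> float:
    """Analytic mean event count of the implemented renewal process.

    By the elementary renewal theorem, E[N(T)] ~ T / E[cycle] where a cycle is
    one gap (``min_gap_s + Exp(theta)``) plus one truncated-lognormal event
    duration; theta is chosen so E[cycle] = 60 / rate_per_min.
    """
    if cfg.sle_rate_per_min == 0:
        return 0.0
    _gap_theta(cfg)  # feasibility check
    return cfg.duration_s * cfg.sle_rate_per_min / 60.0


def _draw_duration(rng: np.random.Generator, cfg: SimRecordingConfig) -> float:
    mu, sig = _lognormal_params(cfg.sle_duration_mean_s, cfg.sle_duration_cv)
    for _ in range(1000):
        d = float(rng.lognormal(mu, sig))
        if d >= MIN_SLE_DURATION_S:
            return d
    return MIN_SLE_DURATION_S  # pathological cv; fall back to the floor


def _draw_events(rng: np.random.Generator, cfg: SimRecordingConfig) -> list[tuple[float, float]]:
    """Event (onset_s, offset_s) pairs of the renewal process on [0, T)."""
    if cfg.sle_rate_per_min == 0:
        return []
    theta = _gap_theta(cfg)
    events: list[tuple[float, float]] = []
    t = 0.0
    while True:
        gap = cfg.min_gap_s + float(rng.exponential(theta))
        dur = _draw_duration(rng, cfg)
        onset = t + gap
        if onset + dur >= cfg.duration_s:
            break
        events.append((onset, onset + dur))
        t = onset + dur
    return events


def _spike_times(
    rng: np.random.Generator, onset: float, offset: float, spike_hz: float, isi_cv: float
) -> np.ndarray:
    """Near-rhythmic trough times within one event."""
    isi_mean = 1.0 / spike_hz
    mu, sig = _lognormal_params(isi_mean, isi_cv)
    times = [onset + 0.5 * isi_mean]
    while True:
        nxt = times[-1] + float(rng.lognormal(mu, sig))
        if nxt > offset - 0.25 * isi_mean:
            break
        times.append(nxt)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# recording assembly
# ---------------------------------------------------------------------------


def _lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    sos = sps.butter(6, cutoff_hz, fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _stamp(trace: np.ndarray, kernel: np.ndarray, center_idx: int) -> None:
    half = (kernel.size - 1) // 2
    lo, hi = center_idx - half, center_idx + half + 1
    klo, khi = max(0, -lo), kernel.size - max(0, hi - trace.size)
    lo, hi = max(0, lo), min(trace.size, hi)
    if lo < hi:
        trace[lo:hi] += kernel[klo:khi]


def simulate_recording(
    config: SimRecordingConfig, recording_id: str = "sim", meta: dict | None = None
) -> tuple[Recording, EventList]:
    """Generate one recording and its ground-truth event list.

    The returned trace has ``duration_s * sampling_rate_hz`` samples.  Spike
    and noise content is band-limited by a zero-phase low-pass at
    ``lowpass_cutoff_hz`` (the acquisition chain's filter); mains hum, which
    physically enters after that filter, is added unfiltered.
    """
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    ss = np.random.SeedSequence(config.seed)
    rng_ev, rng_spk, rng_amp, rng_noise, rng_inter = (
        np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(k,)))
        for k in range(5)
    )
    del ss

    events_s = _draw_events(rng_ev, config)
    spike_kernel_unit = waveform_kernel("spike", 1.0, config.spike_width_s, fs)
    inter_kernel = waveform_kernel(
        "interictal", config.interictal_amplitude, config.interictal_width_s, fs
    )

    impulse = np.zeros(n)
    for onset, offset in events_s:
        for ts in _spike_times(rng_spk, onset, offset, config.intra_sle_spike_hz, config.isi_cv):
            amp_mu, amp_sig = _lognormal_params(config.spike_amplitude, config.spike_amplitude_cv)
            amp = float(rng_amp.lognormal(amp_mu, amp_sig)) if config.spike_amplitude > 0 else 0.0
            _stamp(impulse, amp * spike_kernel_unit, int(round(ts * fs)))

    # interictal spikes: isolated kernels kept clear of events
    if config.interictal_rate_per_min > 0:
        n_inter = rng_inter.poisson(config.interictal_rate_per_min * config.duration_s / 60.0)
        margin = 0.3
        for _ in range(n_inter):
            for _attempt in range(50):
                ts = float(rng_inter.uniform(1.0, config.duration_s - 1.0))
                if all(not (on - margin < ts < off + margin) for on, off in events_s):
                    _stamp(impulse, inter_kernel, int(round(ts * fs)))
                    break

    trace = _lowpass(impulse, config.lowpass_cutoff_hz, fs)

    if config.baseline_noise_sd > 0:
        noise = _lowpass(rng_noise.standard_normal(n), config.lowpass_cutoff_hz, fs)
        trace = trace + noise * (config.baseline_noise_sd / noise.std())

    if config.hum_50hz_amplitude > 0:
        phase = rng_noise.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        trace = trace + config.hum_50hz_amplitude * np.sin(2 * np.pi * 50.0 * t + phase)

    evs = [
        Event(int(round(on * fs)), int(round(off * fs))) for on, off in events_s
    ]
    truth = EventList(evs, fs, config.duration_s)
    rec = Recording(trace, fs, recording_id, dict(meta or {}))
    return rec, truth


def simulate_cohort(config: SimCohortConfig) -> list[SimulatedSlice]:
    """Simulate every slice of a cohort with per-group treatment effects.

    Matched (animal, slice) positions reuse the same per-recording seed in
    every group so paired comparisons isolate the treatment multipliers.
    """
    out: list[SimulatedSlice] = []
    lo, hi = config.slices_per_animal
    for g_idx, (label, effect) in enumerate(config.groups):
        cfg_g = config.base.with_effect(effect)
        g_key = 0 if config.paired_seeds else g_idx + 1
        for a_idx in range(config.animals_per_group):
            rng_a = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(1, g_key, a_idx))
            )
            n_slices = int(rng_a.integers(lo, hi + 1))
            for s_idx in range(n_slices):
                child = np.random.SeedSequence(config.seed, spawn_key=(2, g_key, a_idx, s_idx))
                rec_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
                cfg = replace(cfg_g, seed=rec_seed)
                animal = f"{label}_a{a_idx}"
                slice_id = f"s{s_idx}"
                rec_id = f"{label}_a{a_idx}_s{s_idx}"
                meta = {
                    "group": label,
                    "treatment": label,
                    "hemisphere": "none",
                    "animal_id": animal,
                    "slice_id": slice_id,
                }
                rec, truth = simulate_recording(cfg, rec_id, meta)
                out.append(SimulatedSlice(rec, truth, label, animal, slice_id))
    return out
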