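"""End-to-end orchestration: simulate -> train -> predict -> correct ->
metrics -> PSD -> stats, emitting a self-describing results bundle.

Configuration is a nested mapping (YAML or JSON).  Every stage constant of
the analysis chain appears exactly once as a named default in
:data:`CONFIG_SCHEMA`; unknown keys are rejected before any compute.  The
global seed deterministically derives every stage's randomness, so re-running
a config reproduces the rule-based tables exactly (and training within
float32 tolerance).
"""

from __future__ import annotations

import json
import logging
import time
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as met
from . import spectral as spec
from . import stats as gstats
from .detector import SLEDetector
from .io import LabelSeries, downsample, write_events, write_recording
from .nn import save_model
from .postprocess import PostprocessConfig, correct, events_to_labels
from .synth import SimCohortConfig, SimRecordingConfig, TreatmentEffect, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["CONFIG_SCHEMA", "validate_config", "run_pipeline", "compute_stats_tables", "ConfigError"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


# Defaults of the full analysis chain. Analysis constants: 40-min analysis
# window (minutes 100-140), 125-Hz label rate, 30-s segments, drop < 0.1 s,
# merge < 0.2 s, 0.165-s spike window, 0.2-Hz bins over (0, 30] Hz, 1e4
# bootstrap resamples, 100 epochs with patience 2 and learning-rate factor
# 10, pauses > 120 s.
CONFIG_SCHEMA: dict = {
    "seed": 0,
    "output_dir": "results",
    "verbosity": "info",
    "analysis_window": {"start_min": 100.0, "end_min": 140.0},
    "simulate": {
        "groups": [
            {"label": "ctrl", "duration_multiplier": 1.0, "spike_freq_multiplier": 1.0, "rate_multiplier": 1.0},
            {"label": "CNB120", "duration_multiplier": 0.3, "spike_freq_multiplier": 0.8, "rate_multiplier": 1.2},
        ],
        "animals_per_group": 3,
        "slices_per_animal": [2, 6],
        "paired_seeds": True,
        "duration_s": 600.0,
        "sampling_rate_hz": 2000.0,
        "sle_rate_per_min": 12.0,
        "sle_duration_mean_s": 2.0,
        "sle_duration_cv": 0.5,
        "intra_sle_spike_hz": 10.0,
        "spike_amplitude": 8.0,
        "min_gap_s": 0.1,
        "baseline_noise_sd": 1.0,
        "lowpass_cutoff_hz": 30.0,
        "interictal_rate_per_min": 2.0,
        "hum_50hz_amplitude": 0.0,
    },
    "detector": {
        "label_rate_hz": 125.0,
        "segment_s": 30.0,
        "n_blocks": 8,
        "channels": 16,
        "padding_mode": "symmetric",
        "epochs": 100,
        "initial_learning_rate": 1.0e-3,
        "plateau_patience_epochs": 2,
        "lr_decay_factor": 10.0,
        "batch_size": 32,
        "val_fraction": 0.2,
        "augment_noise": True,
    },
    "postprocess": {
        "binarize_threshold": 0.5,
        "min_duration_s": 0.1,
        "merge_gap_s": 0.2,
    },
    "metrics": {
        "spike_window_s": 0.165,
        "pause_min_s": 120.0,
    },
    "psd": {
        "bin_width_hz": 0.2,
        "band_max_hz": 30.0,
        "n_resamples": 10000,
        "confidence_level": 0.95,
        "normalized": True,
    },
    "stats": {
        "metrics": ["fraction", "mean_duration_s", "rate_per_min", "spike_freq_hz"],
        "control_group": "ctrl",
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = deepcopy(defaults)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and key != "groups":
            if not isinstance(val, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


def validate_config(path_or_mapping: str | Path | dict | None = None) -> dict:
    """Normalize a YAML/JSON config file (or mapping): fill defaults, reject
    unknown keys, and sanity-check nested values by instantiating the typed
    stage configs."""
    if path_or_mapping is None:
        raw: dict = {}
    elif isinstance(path_or_mapping, dict):
        raw = path_or_mapping
    else:
        text = Path(path_or_mapping).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration root must be a mapping")
    cfg = _merge(CONFIG_SCHEMA, raw)
    _cohort_config(cfg)  # raises on invalid nested values before any compute
    PostprocessConfig(**cfg["postprocess"])
    return cfg


def _cohort_config(cfg: dict) -> SimCohortConfig:
    sim = cfg["simulate"]
    groups = tuple(
        (
            g["label"],
            TreatmentEffect(
                g.get("duration_multiplier", 1.0),
                g.get("spike_freq_multiplier", 1.0),
                g.get("rate_multiplier", 1.0),
            ),
        )
        for g in sim["groups"]
    )
    base = SimRecordingConfig(
        duration_s=sim["duration_s"],
        sampling_rate_hz=sim["sampling_rate_hz"],
        sle_rate_per_min=sim["sle_rate_per_min"],
        sle_duration_mean_s=sim["sle_duration_mean_s"],
        sle_duration_cv=sim["sle_duration_cv"],
        intra_sle_spike_hz=sim["intra_sle_spike_hz"],
        spike_amplitude=sim["spike_amplitude"],
        min_gap_s=sim["min_gap_s"],
        baseline_noise_sd=sim["baseline_noise_sd"],
        lowpass_cutoff_hz=sim["lowpass_cutoff_hz"],
        interictal_rate_per_min=sim["interictal_rate_per_min"],
        hum_50hz_amplitude=sim["hum_50hz_amplitude"],
        seed=cfg["seed"],
    )
    return SimCohortConfig(
        groups=groups,
        animals_per_group=sim["animals_per_group"],
        slices_per_animal=tuple(sim["slices_per_animal"]),
        base=base,
        seed=cfg["seed"],
        paired_seeds=sim["paired_seeds"],
    )


def compute_stats_tables(
    tables: dict[str, pd.DataFrame],
    metrics: list[str],
    control_group: str,
) -> pd.DataFrame:
    """Group comparisons (control vs each other group) for each metric and
    aggregation level; deterministic given the metric tables, so a bundle's
    stats CSV can be reproduced from its metric CSVs."""
    stats_rows = []
    for level, table in tables.items():
        groups = sorted(table["group"].unique())
        pairs = [(control_group, g) for g in groups if g != control_group] if control_group in groups else None
        for metric in metrics:
            try:
                res = gstats.compare_metric_across_groups(table, metric, "group", pairs)
            except ValueError:
                continue
            for c in res.pairwise:
                stats_rows.append(
                    {
                        "level": level,
                        "metric": metric,
                        "omnibus_H": res.statistic,
                        "omnibus_p": res.p_value,
                        "pair": f"{c.group_a}:{c.group_b}",
                        "z": c.z,
                        "p_raw": c.p_raw,
                        "p_adj": c.p_adjusted,
                        "stars": c.stars,
                    }
                )
    return pd.DataFrame(stats_rows)


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **fields) -> None:
        rec = {"stage": stage, "time": time.time(), **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def run_pipeline(config: dict | str | Path | None = None) -> dict:
    """Run every stage and write the results bundle to ``output_dir``.

    Returns a dict with in-memory handles (tables, model, band per group)
    plus the bundle path.  Any stage error propagates with the stage name in
    the log.
    """
    cfg = validate_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.jsonl")
    log.event("start", seed=cfg["seed"], config=cfg)
    t0 = time.time()

    # -- simulate ----------------------------------------------------------
    cohort = simulate_cohort(_cohort_config(cfg))
    manifest = pd.DataFrame(
        [
            {
                "recording_id": s.recording.recording_id,
                "group": s.group,
                "animal_id": s.animal_id,
                "slice_id": s.slice_id,
                "duration_s": s.recording.duration_s,
                "n_truth_events": len(s.truth),
            }
            for s in cohort
        ]
    )
    manifest.to_csv(out / "dataset_manifest.csv", index=False)
    ev_dir = out / "truth_events"
    ev_dir.mkdir(exist_ok=True)
    for s in cohort:
        write_events(s.truth, ev_dir / f"{s.recording.recording_id}.tsv")
    log.event("simulate", n_recordings=len(cohort), wall_s=time.time() - t0)

    # -- downsample + labels ----------------------------------------------
    det_cfg = cfg["detector"]
    rate = det_cfg["label_rate_hz"]
    recs125 = [downsample(s.recording, rate) for s in cohort]
    labels = [
        LabelSeries(events_to_labels(s.truth.at_rate(rate), r.n_samples).labels, rate)
        for s, r in zip(cohort, recs125)
    ]

    # -- train -------------------------------------------------------------
    t1 = time.time()
    det = SLEDetector(
        n_blocks=det_cfg["n_blocks"],
        channels=det_cfg["channels"],
        padding_mode=det_cfg["padding_mode"],
        input_rate_hz=rate,
        segment_s=det_cfg["segment_s"],
        epochs=det_cfg["epochs"],
        initial_learning_rate=det_cfg["initial_learning_rate"],
        plateau_patience_epochs=det_cfg["plateau_patience_epochs"],
        lr_decay_factor=det_cfg["lr_decay_factor"],
        batch_size=det_cfg["batch_size"],
        val_fraction=det_cfg["val_fraction"],
        augment_noise=det_cfg["augment_noise"],
        binarize_threshold=cfg["postprocess"]["binarize_threshold"],
        random_state=cfg["seed"],
    )
    det.fit(recs125, labels)
    det.history_.to_csv(out / "training_history.csv", index=False)
    save_model(det.model_, out / "model.npz")
    log.event(
        "train",
        n_parameters=det.n_parameters_,
        best_corrected_val_accuracy=float(det.history_["corrected_val_accuracy"].max()),
        wall_s=time.time() - t1,
    )

    # -- predict + correct -------------------------------------------------
    t1 = time.time()
    pp = PostprocessConfig(**cfg["postprocess"])
    pred_dir = out / "predicted_events"
    pred_dir.mkdir(exist_ok=True)
    predicted = []
    for s, r in zip(cohort, recs125):
        events = correct(det.predict(r), r, pp)
        predicted.append(events)
        write_events(events, pred_dir / f"{s.recording.recording_id}.tsv")
    log.event("predict", wall_s=time.time() - t1)

    # -- metrics -----------------------------------------------------------
    rows = []
    for s, events125 in zip(cohort, predicted):
        events_full = events125.at_rate(s.recording.sampling_rate_hz)
        rows.append((s.recording, events_full))
    table_slice = met.metrics_table(rows, window_s=cfg["metrics"]["spike_window_s"])
    table_slice.to_csv(out / "metrics_slice.csv", index=False)
    table_animal = met.aggregate(table_slice, "animal")
    table_animal.to_csv(out / "metrics_animal.csv", index=False)
    log.event("metrics", n_slices=len(table_slice), n_animals=len(table_animal))

    # -- PSD ---------------------------------------------------------------
    t1 = time.time()
    psd_cfg = cfg["psd"]
    binner = spec.PSDBinner(psd_cfg["bin_width_hz"], psd_cfg["normalized"])
    bands = {}
    psd_rows = []
    groups = sorted({s.group for s in cohort})
    rng_children = np.random.SeedSequence(cfg["seed"], spawn_key=(11,)).generate_state(len(groups))
    for g, g_seed in zip(groups, rng_children):
        g_psds = binner.transform([s.recording for s in cohort if s.group == g])
        band = spec.bootstrap_band(
            g_psds,
            n_resamples=psd_cfg["n_resamples"],
            level=psd_cfg["confidence_level"],
            seed=int(g_seed % (2**31 - 1)),
        )
        bands[g] = band
        for c, m, lo, hi in zip(band.bin_centers_hz, band.mean, band.lower, band.upper):
            psd_rows.append({"group": g, "bin_center_hz": c, "mean": m, "lower": lo, "upper": hi})
    pd.DataFrame(psd_rows).to_csv(out / "psd_bands.csv", index=False)
    log.event("psd", wall_s=time.time() - t1)

    # -- stats -------------------------------------------------------------
    stats_table = compute_stats_tables(
        {"slice": table_slice, "animal": table_animal},
        cfg["stats"]["metrics"],
        cfg["stats"]["control_group"],
    )
    stats_table.to_csv(out / "stats.csv", index=False)
    log.event("stats", n_comparisons=len(stats_table))
    log.event("done", wall_s=time.time() - t0)

    return {
        "output_dir": out,
        "manifest": manifest,
        "detector": det,
        "metrics_slice": table_slice,
        "metrics_animal": table_animal,
        "psd_bands": bands,
        "stats": stats_table,
    }
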