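"""End-to-end orchestration: simulate/ingest -> preprocess -> per-(well,
session) forecaster -> graphs -> descriptors -> normalize -> select ->
classify, driven by one config and one master seed.

Each (well, session) recording trains its own forecaster on the first half
of the recording and yields attention graphs from the second half, so a
plate of 6 wells x 4 sessions produces 24 trained models. All randomness is
routed through a master seed expanded per stage and per recording.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification as clf_mod
from . import feature_selection as fs_mod
from . import gdn_model as gdn
from . import graph_descriptors as gd
from . import preprocessing as pre
from . import synthetic_mea as syn
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    # simulation (used when no input recordings are given)
    n_ctrl_wells: int = 4
    n_treated_wells: int = 3
    sessions: tuple = ("0h", "30min", "24h", "48h")
    scenario: dict = field(default_factory=dict)

    # preprocessing
    low_hz: float = 200.0
    high_hz: float = 3000.0
    threshold_factor: float = 4.5
    threshold_window_ms: float = 50.0
    kaiser_beta: float = 10.0
    block_ms: float = 20.0
    am_ms: float = 18.0
    window_T: int = 56

    # forecaster
    gdn: dict = field(default_factory=dict)
    tau: float | None = None

    # descriptors / selection / classification
    descriptor_set: str = "retained19"
    percentile: float = 95.0
    ds_cut: float = 0.75
    ds_agg: str = "max"
    classifier: str = "lda"

    # scale control: cap on AM-spike segments used per recording half.
    # max_segments bounds the graph-extraction (descriptor) half, which
    # dominates runtime; max_train_segments, when set, bounds the training
    # half separately (it defaults to the same cap).
    max_segments: int | None = None
    max_train_segments: int | None = None

    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sessions"] = list(self.sessions)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def validate_config(raw: dict | PipelineConfig) -> PipelineConfig:
    """Fill defaults, check ranges and echo the effective config."""
    cfg = raw if isinstance(raw, PipelineConfig) else PipelineConfig(**raw)
    for s in cfg.sessions:
        if s not in pre.SESSIONS:
            raise ConfigError(f"unknown session label {s!r}; allowed: {pre.SESSIONS}")
    if "0h" not in cfg.sessions:
        raise ConfigError("the 0h baseline session is required for normalization")
    if cfg.classifier not in clf_mod.CLASSIFIER_NAMES:
        raise ConfigError(
            f"unknown classifier {cfg.classifier!r}; allowed: {clf_mod.CLASSIFIER_NAMES}")
    if cfg.descriptor_set not in ("retained19", "full35"):
        raise ConfigError("descriptor_set must be 'retained19' or 'full35'")
    if cfg.gdn.get("epochs", 1) <= 0:
        raise ConfigError("epochs must be positive")
    if cfg.scenario.get("base_rate_hz", 0.0) < 0:
        raise ConfigError("firing rate must be non-negative")
    # constructing the nested configs validates the remaining ranges
    syn.SimulationScenario(**cfg.scenario)
    return cfg


def _derive_seed(master: int, *tokens) -> int:
    h = hashlib.sha256(("|".join(map(str, (master,) + tokens))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def process_recording(rec: pre.Recording, cfg: PipelineConfig,
                      gdn_seed: int) -> dict:
    """Preprocess one recording, train its forecaster on the first half and
    extract descriptor time series from the second half."""
    filtered = pre.bandpass_filter(rec, low_hz=cfg.low_hz, high_hz=cfg.high_hz)
    thresholds = pre.estimate_thresholds(filtered, window_ms=cfg.threshold_window_ms,
                                         factor=cfg.threshold_factor)
    events = pre.detect_spikes(filtered, thresholds)
    ev_train, ev_test = pre.split_events_by_half(events, filtered.n_samples)
    train_cap = (cfg.max_train_segments if cfg.max_train_segments is not None
                 else cfg.max_segments)
    if train_cap is not None:
        ev_train = ev_train[:train_cap]
    if cfg.max_segments is not None:
        ev_test = ev_test[: cfg.max_segments]
    if not ev_train or not ev_test:
        raise DataError(f"{rec.well_id}/{rec.session}: too few events to split")
    train_am = pre.build_am_spike_train(filtered, ev_train,
                                        block_s=cfg.block_ms * 1e-3,
                                        crop_s=cfg.am_ms * 1e-3,
                                        beta=cfg.kaiser_beta)
    test_am = pre.build_am_spike_train(filtered, ev_test,
                                       block_s=cfg.block_ms * 1e-3,
                                       crop_s=cfg.am_ms * 1e-3,
                                       beta=cfg.kaiser_beta)
    train_batch = pre.segment_windows(train_am, T=cfg.window_T)
    test_batch = pre.segment_windows(test_am, T=cfg.window_T)

    gdn_cfg = gdn.GDNConfig(n_channels=rec.n_channels, window=cfg.window_T,
                            seed=gdn_seed, **cfg.gdn)
    model, history = gdn.train_gdn(train_batch, gdn_cfg)
    snapshots = gdn.extract_graphs(model, test_batch, tau=cfg.tau)
    series = gd.descriptor_timeseries(snapshots, well_id=rec.well_id,
                                      session=rec.session, condition=rec.condition)
    report = gdn.evaluate_forecast(model, test_batch, split="test")
    return {"model": model, "history": history, "snapshots": snapshots,
            "features": series.table, "forecast_report": report,
            "n_events": len(events), "n_train_segments": train_am.n_segments,
            "n_test_segments": test_am.n_segments}


def run_pipeline(config: dict | PipelineConfig,
                 recordings: list | None = None) -> dict:
    """Run every stage and return a report bundle.

    ``recordings`` may supply pre-made Recording objects (e.g. loaded from
    HDF5); otherwise a synthetic plate is generated from the config scenario.
    When ``out_dir`` is set, models, feature tables, the selection and the
    classification results are written there along with the effective config.
    """
    cfg = validate_config(config)
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "models").mkdir(exist_ok=True)
        with open(out_dir / "config.json", "w") as f:
            json.dump({"config": cfg.to_dict(), "hash": cfg.config_hash()}, f, indent=2)

    if recordings is None:
        scenario = syn.SimulationScenario(seed=_derive_seed(cfg.seed, "simulate"),
                                          **cfg.scenario)
        plate = syn.simulate_plate(cfg.n_ctrl_wells, cfg.n_treated_wells,
                                   sessions=cfg.sessions, scenario=scenario)
        recordings = [rec for rec, _gt in plate]

    feature_blocks = []
    per_recording = {}
    for rec in recordings:
        key = f"{rec.well_id}_{rec.session}"
        res = process_recording(rec, cfg, _derive_seed(cfg.seed, "gdn", key))
        per_recording[key] = res
        feature_blocks.append(res["features"])
        if out_dir:
            res["model"].save(out_dir / "models" / f"gdn_{key}.npz")
    features = pd.concat(feature_blocks, ignore_index=True)
    if out_dir:
        features.to_csv(out_dir / "features.csv", index=False)

    feature_cols = list(gd.RETAINED_19 if cfg.descriptor_set == "retained19"
                        else gd.FULL_35)
    normalized = fs_mod.baseline_normalize(features, feature_cols)

    sessions = [s for s in cfg.sessions if s != "0h"]
    selections, session_results = {}, {}
    for session in sessions:
        selection, ds = fs_mod.select(normalized, feature_cols, session,
                                      percentile=cfg.percentile,
                                      ds_cut=cfg.ds_cut, agg=cfg.ds_agg)
        selections[session] = selection
        if not selection.offsets or not selection.features:
            session_results[session] = {"error": "empty selection"}
            continue
        samples = clf_mod.build_samples(normalized, selection)
        folds = clf_mod.lowo_cv(samples, classifier=cfg.classifier,
                                seed=_derive_seed(cfg.seed, "clf", session))
        session_results[session] = {
            "selection": selection.to_dict(),
            "n_rows": len(samples),
            "single_accuracy": clf_mod.pooled_accuracy(folds),
            "majority_accuracy": clf_mod.majority_accuracy(folds),
            "confusion_rows": clf_mod.confusion_matrix(folds).to_dict(),
            "confusion_wells": clf_mod.confusion_matrix(folds, per_well=True).to_dict(),
        }

    report = {
        "config_hash": cfg.config_hash(),
        "n_models": len(per_recording),
        "per_recording": per_recording,
        "features": features,
        "normalized": normalized,
        "selections": selections,
        "sessions": session_results,
    }
    if out_dir:
        with open(out_dir / "selection.json", "w") as f:
            json.dump({s: sel.to_dict() for s, sel in selections.items()}, f, indent=2)
        serializable = {s: {k: v for k, v in r.items()}
                        for s, r in session_results.items()}
        with open(out_dir / "results.json", "w") as f:
            json.dump({"config_hash": cfg.config_hash(),
                       "n_models": len(per_recording),
                       "sessions": serializable}, f, indent=2)
    return report
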