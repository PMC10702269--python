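"""End-to-end orchestration: simulate -> label -> segments -> features ->
statistics -> prediction, with a checksum manifest so unchanged stages are
skipped on re-runs.

The library entry points here are also what the tests and the CLI use:
``compute_patient_features`` turns one recording plus its annotations into
the per-seizure 10-feature table, and ``run_all`` executes every stage into
a run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import predict as pr
from . import stats as st
from .config import PipelineConfig, config_fingerprint, dump_resolved
from .events import SeizureEvent, read_annotations, frame_to_events
from .preprocess import (
    MontageLayout,
    extract_windows,
    make_bipolar,
    segment_and_filter,
)
from .ren import assemble_features, grand_average, ren_all_pairs
from .synthetic import Recording, load_recording, save_dataset, simulate
from .taxonomy import (
    TASKS,
    TaxonomyConfig,
    label_seizures,
    labels_to_frame,
    patient_eligible,
)

logger = logging.getLogger(__name__)


def iter_segment_tensors(
    rec: Recording,
    events: Sequence[SeizureEvent],
    cfg: PipelineConfig,
):
    """Yield the (window, SegmentTensor) stream for one patient."""
    layout: MontageLayout = cfg.sim.layout
    windows = extract_windows(events, near_window_s=cfg.preprocess.near_window_s)
    for win in windows:
        if win.length_s <= 0:
            continue
        raw = rec.slice(win.start_s, win.end_s)
        bipolar = make_bipolar(raw, layout)
        yield win, segment_and_filter(
            bipolar, win, rec.fs, bands=cfg.bands,
            segment_len_s=cfg.preprocess.segment_len_s,
        )


def compute_patient_features(
    rec: Recording,
    events: Sequence[SeizureEvent],
    labels_frame: pd.DataFrame,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """One patient's per-seizure grand-average REN feature table."""
    from .events import events_to_frame

    per_seizure: dict[int, dict[str, dict[str, float]]] = {}
    for win, seg in iter_segment_tensors(rec, events, cfg):
        ga = grand_average(ren_all_pairs(seg, cfg.ren))
        if ga:
            per_seizure.setdefault(win.seizure_index, {})[win.period] = ga
    return assemble_features(per_seizure, events_to_frame(events), labels_frame)


def label_annotations(
    annotations: pd.DataFrame, cfg: TaxonomyConfig
) -> pd.DataFrame:
    """Annotation table augmented with per-seizure taxonomy columns."""
    out = []
    for pid, sub in annotations.groupby("patient_id", sort=True):
        sub = sub.sort_values("onset_s").reset_index(drop=True)
        events = frame_to_events(sub)
        lab = labels_to_frame(label_seizures(events, cfg))
        out.append(pd.concat([sub, lab], axis=1))
    return pd.concat(out, ignore_index=True)


def save_segment_store(
    rec: Recording,
    events: Sequence[SeizureEvent],
    cfg: PipelineConfig,
    out: str | Path,
) -> pd.DataFrame:
    """Write one patient's segments as a compressed array container.

    The ``.npz`` holds ``data_<i>_<period>`` / ``valid_<i>_<period>`` arrays;
    the returned index frame (one row per stored tensor) is written by the
    caller next to it.
    """
    arrays: dict[str, np.ndarray] = {}
    rows = []
    for win, seg in iter_segment_tensors(rec, events, cfg):
        key = f"{win.seizure_index}_{win.period}"
        arrays[f"data_{key}"] = seg.data.astype(np.float32)
        arrays[f"valid_{key}"] = seg.valid
        rows.append(
            {
                "seizure_index": win.seizure_index,
                "period": win.period,
                "n_segments": seg.n_segments,
                "fs": seg.fs,
                "bands": ",".join(seg.band_names),
            }
        )
    np.savez_compressed(out, **arrays)
    return pd.DataFrame(rows)


def load_segment_store(path: str | Path, index: pd.DataFrame):
    """Yield SegmentTensors back from a segments ``.npz`` + index frame."""
    from .preprocess import SegmentTensor

    with np.load(path) as npz:
        for row in index.itertuples(index=False):
            key = f"{row.seizure_index}_{row.period}"
            yield SegmentTensor(
                int(row.seizure_index),
                row.period,
                npz[f"data_{key}"].astype(np.float64),
                float(row.fs),
                tuple(row.bands.split(",")),
                valid=npz[f"valid_{key}"],
            )


# ---------------------------------------------------------------------------
# staged run directory with checksum manifest


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class _Stage:
    def __init__(self, run_dir: Path, name: str, fingerprint: dict):
        self.dir = run_dir / name
        self.name = name
        self.fingerprint = fingerprint
        self.manifest = self.dir / "manifest.json"

    def is_current(self) -> bool:
        if not self.manifest.exists():
            return False
        try:
            return json.loads(self.manifest.read_text()) == self.fingerprint
        except json.JSONDecodeError:
            return False

    def finish(self) -> None:
        self.manifest.write_text(json.dumps(self.fingerprint, indent=1))


def run_all(cfg: PipelineConfig, run_dir: str | Path) -> dict[str, str]:
    """Execute every pipeline stage into ``run_dir``.

    Each stage writes a manifest of its config subset and input checksums;
    a re-run with unchanged manifest skips the stage. Returns a mapping
    stage -> "ran" | "skipped".
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    dump_resolved(cfg, run_dir / "resolved_config.json")
    status: dict[str, str] = {}

    # -- simulate ----------------------------------------------------------
    sim_stage = _Stage(run_dir, "simulate", {"config": config_fingerprint(cfg.sim)})
    sim_dir = sim_stage.dir
    if sim_stage.is_current():
        status["simulate"] = "skipped"
    else:
        sim_dir.mkdir(parents=True, exist_ok=True)
        ds = simulate(cfg.sim)
        save_dataset(ds, sim_dir)
        sim_stage.finish()
        status["simulate"] = "ran"
    ann_path = sim_dir / "annotations.csv"
    annotations = read_annotations(ann_path)
    n_patients = annotations.patient_id.nunique()
    logger.info("annotations: %d seizures, %d patients", len(annotations), n_patients)

    # -- label -------------------------------------------------------------
    label_stage = _Stage(
        run_dir,
        "label",
        {"config": config_fingerprint(cfg.taxonomy), "annotations": _file_hash(ann_path)},
    )
    labeled_path = label_stage.dir / "labeled.csv"
    if label_stage.is_current():
        status["label"] = "skipped"
    else:
        label_stage.dir.mkdir(parents=True, exist_ok=True)
        label_annotations(annotations, cfg.taxonomy).to_csv(labeled_path, index=False)
        label_stage.finish()
        status["label"] = "ran"
    labeled = pd.read_csv(labeled_path)

    # -- features (preprocess + REN fused: segments stream straight in) ----
    feat_fp = {
        "config": config_fingerprint(
            {"pre": cfg.preprocess, "ren": cfg.ren, "bands": [b.name for b in cfg.bands]}
        ),
        "annotations": _file_hash(ann_path),
        "labels": _file_hash(labeled_path),
    }
    feat_stage = _Stage(run_dir, "features", feat_fp)
    features_path = feat_stage.dir / "features.csv"
    if feat_stage.is_current():
        status["features"] = "skipped"
    else:
        feat_stage.dir.mkdir(parents=True, exist_ok=True)
        frames = []
        for pid, sub in labeled.groupby("patient_id", sort=True):
            sub = sub.sort_values("onset_s").reset_index(drop=True)
            rec = load_recording(sim_dir / str(pid))
            events = frame_to_events(sub)
            frames.append(compute_patient_features(rec, events, sub, cfg))
        pd.concat(frames, ignore_index=True).to_csv(features_path, index=False)
        feat_stage.finish()
        status["features"] = "ran"
    features = pd.read_csv(features_path)

    # -- stats -------------------------------------------------------------
    stats_stage = _Stage(
        run_dir, "stats", {"features": _file_hash(features_path)}
    )
    if stats_stage.is_current():
        status["stats"] = "skipped"
    else:
        stats_stage.dir.mkdir(parents=True, exist_ok=True)
        band_names = [b.name for b in cfg.bands]
        cells = st.compare_groups(features, band_names)
        st.cells_to_frame(cells).to_csv(stats_stage.dir / "cells.csv", index=False)
        tally = st.direction_tally(cells)
        summary = {
            "n_cells": len(cells),
            "n_significant": int(sum(c.significant for c in cells)),
            "direction_tally": tally.to_dict(orient="records"),
        }
        (stats_stage.dir / "summary.json").write_text(json.dumps(summary, indent=1))
        stats_stage.finish()
        status["stats"] = "ran"

    # -- predict -----------------------------------------------------------
    pred_stage = _Stage(
        run_dir,
        "predict",
        {"config": config_fingerprint(cfg.cv), "features": _file_hash(features_path)},
    )
    if pred_stage.is_current():
        status["predict"] = "skipped"
    else:
        pred_stage.dir.mkdir(parents=True, exist_ok=True)
        fold_frames = []
        baseline_rows = []
        for task in TASKS:
            for pid, sub in features.groupby("patient_id", sort=True):
                events = frame_to_events(
                    labeled[labeled.patient_id == pid].sort_values("onset_s")
                )
                labs = label_seizures(events, cfg.taxonomy)
                ok, reason = patient_eligible(labs, task)
                if not ok:
                    logger.info("patient %s: %s", pid, reason)
                    continue
                report = pr.run_task(sub, task, cfg.cv)
                folds = report.folds.assign(patient_id=pid, task=task)
                fold_frames.append(folds)
                baseline_rows.append(
                    {"patient_id": pid, "task": task, **report.baselines.as_percent_row()}
                )
        if fold_frames:
            pd.concat(fold_frames, ignore_index=True).to_csv(
                pred_stage.dir / "folds.csv", index=False
            )
        pd.DataFrame(baseline_rows).to_csv(pred_stage.dir / "baselines.csv", index=False)
        pred_stage.finish()
        status["predict"] = "ran"

    logger.info("run_all: %s", status)
    return status
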