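"""End-to-end orchestration: simulate -> preprocess -> extract -> select/train/eval.

A :class:`PipelineConfig` (plain dataclasses, YAML/JSON serializable)
plus a seed fully determines a run.  The root seed fans out into
per-subject simulation substreams and the split/CV seeds, so any stage or
subject is reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from painfeat.core import write_feature_matrix, write_recording, write_schedule
from painfeat.classify import TASKS, PainClassificationTask, SVMConfig, SplitSpec
from painfeat.features import FeatureConfig, extract_features, znorm_per_person
from painfeat.preprocess import preprocess_subject
from painfeat.simulate import SimConfig, iter_dataset

log = logging.getLogger(__name__)

DEFAULT_TASKS = tuple(TASKS)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    tasks: tuple[str, ...] = DEFAULT_TASKS
    out_dir: str = "painfeat_run"
    window_s: float = 5.5
    emd_windows: bool = True
    max_selected: int | None = 22
    keep_classes: tuple[str, ...] | None = None  # restrict extraction, None = all

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def _sub(klass, key):
            d = dict(raw.get(key, {}))
            for k, v in d.items():
                if isinstance(v, list):
                    d[k] = tuple(v)
            return klass(**d)

        cfg = cls(
            sim=_sub(SimConfig, "sim"),
            features=_sub(FeatureConfig, "features"),
            svm=_sub(SVMConfig, "svm"),
            split=_sub(SplitSpec, "split"),
        )
        for k in ("tasks", "out_dir", "window_s", "emd_windows", "max_selected",
                  "keep_classes"):
            if k in raw:
                v = raw[k]
                setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def build_feature_matrix(cfg: PipelineConfig, write_raw_to: Path | None = None
                         ) -> pd.DataFrame:
    """simulate -> preprocess -> extract -> per-person z-normalization."""

    def _subjects():
        for rec, schedule in iter_dataset(cfg.sim):
            t0 = time.perf_counter()
            if write_raw_to is not None:
                write_recording(rec, write_raw_to / f"{rec.subject_id}_signals.csv",
                                write_raw_to / f"{rec.subject_id}_meta.json")
                write_schedule(schedule, write_raw_to / f"{rec.subject_id}_events.csv")
            pre = preprocess_subject(rec, schedule, window_s=cfg.window_s,
                                     emd_windows=cfg.emd_windows,
                                     keep_classes=cfg.keep_classes)
            log.info("subject %s: %d windows preprocessed in %.1fs",
                     rec.subject_id, len(pre.windows), time.perf_counter() - t0)
            yield pre

    matrix = extract_features(_subjects(), cfg.features)
    return znorm_per_person(matrix)


def run_all(cfg: PipelineConfig) -> Path:
    """Full pipeline run; returns the run directory with all artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2, default=list))

    t0 = time.perf_counter()
    matrix = build_feature_matrix(cfg)
    write_feature_matrix(matrix, out / "features.tsv")
    log.info("feature matrix %s written in %.1fs", matrix.shape,
             time.perf_counter() - t0)

    summary = {"n_rows": len(matrix),
               "n_features": len(matrix.columns) - 2,
               "tasks": {}}
    for task in cfg.tasks:
        t1 = time.perf_counter()
        results = PainClassificationTask(
            matrix, task, svm_config=cfg.svm, split=cfg.split,
            max_selected=cfg.max_selected).fit()
        results.report.to_json(out / f"report_{task}.json")
        (out / f"selection_{task}.json").write_text(
            json.dumps(results.selection.to_dict(), indent=2))
        summary["tasks"][task] = {
            "accuracy": results.report.accuracy,
            "cramers_v": results.report.cramers_v,
            "n_selected": len(results.report.selected_features),
            "svm_params": list(results.report.svm_params),
            "runtime_s": round(time.perf_counter() - t1, 2),
        }
        log.info("task %s: accuracy %.3f (%.1fs)", task,
                 results.report.accuracy, time.perf_counter() - t1)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
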