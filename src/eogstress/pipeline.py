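"""End-to-end orchestration: simulate -> preprocess -> blinks -> features ->
select -> train -> evaluate, as one configured, logged, reproducible run.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence((global_seed, stage_index))``, so stages are
independently reproducible. Every run writes a manifest listing each
stage's configuration fingerprint and every output file with its SHA-256
content hash; rerunning the same configuration reproduces identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, features, modeling
from .blinks import detect_blinks, events_to_rows
from .io import write_session_csv
from .preprocessing import FilterSpec, preprocess_session
from .synthetic import SynthConfig, generate_cohort

STAGES = ["simulate", "preprocess", "blinks", "features", "select", "train", "evaluate"]


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    filter_spec: FilterSpec | None = None
    guard_s: float = 0.5
    window_s: float = 3.0
    step_s: float = 1.0
    classifiers: tuple[str, ...] = ("rf", "lr", "svm", "dt", "knn")
    class_schemes: tuple[str, ...] = ("two", "three")
    protocols: tuple[str, ...] = ("kfold10", "loso")
    tune: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        fspec = raw.pop("filter", None)
        filter_spec = FilterSpec(**fspec) if fspec else None
        return cls(synth=synth, filter_spec=filter_spec, **raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence((global_seed, idx))
    return int(ss.generate_state(1)[0] % (2**31))


def _config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> tuple[dict, dict]:
    """Execute every stage; returns (reports, manifest).

    Reports are also written under ``out_dir`` (JSON + CSV tables) and the
    manifest as ``manifest.json``. Any stage failure aborts with the stage
    name and the fingerprint of its input configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}

    def record(stage: str, cfg, outputs: list[Path]):
        manifest["stages"].append({"stage": stage, "config_hash": _config_hash(cfg)})
        for p in outputs:
            manifest["files"][str(p.relative_to(out))] = _file_hash(p)

    def run_stage(stage: str, cfg, fn):
        try:
            return fn()
        except Exception as exc:  # annotate failures with stage + fingerprint
            raise RuntimeError(
                f"pipeline stage '{stage}' failed (config {_config_hash(cfg)}): {exc}"
            ) from exc

    # 1. simulate
    synth = dataclasses.replace(config.synth, seed=stage_seed(config.seed, "simulate"))
    cohort = run_stage("simulate", synth, lambda: generate_cohort(synth))
    session_dir = out / "sessions"
    session_dir.mkdir(exist_ok=True)
    session_files = []
    for session, truth in cohort:
        p = write_session_csv(session, session_dir / f"{session.subject_id}.csv", truth)
        session_files.extend([p, p.with_suffix(".json")])
    record("simulate", synth, session_files)

    # 2. preprocess
    fspec = config.filter_spec or FilterSpec(sampling_rate=synth.sampling_rate)
    cleaned = run_stage(
        "preprocess", fspec,
        lambda: [preprocess_session(s, fspec, config.guard_s) for s, _ in cohort],
    )
    prep_log = {
        s.subject_id: p.log for (s, _), p in zip(cohort, cleaned)
    }
    prep_path = out / "preprocessing_log.json"
    prep_path.write_text(json.dumps(prep_log, indent=1, sort_keys=True))
    record("preprocess", fspec, [prep_path])

    # 3. blink detection
    blink_cfg = {"template_duration_s": 0.3}
    all_events = run_stage(
        "blinks", blink_cfg,
        lambda: [detect_blinks(p.eog_v, s.sampling_rate) for (s, _), p in zip(cohort, cleaned)],
    )
    blink_path = out / "blinks.csv"
    blink_rows = []
    for (session, _), events in zip(cohort, all_events):
        for row in events_to_rows(events):
            blink_rows.append({"subject_id": session.subject_id, **row})
    pd.DataFrame(blink_rows).to_csv(blink_path, index=False, float_format="%.9g")
    record("blinks", blink_cfg, [blink_path])

    # 4. features
    win_cfg = {"window_s": config.window_s, "step_s": config.step_s}
    tables = run_stage(
        "features", win_cfg,
        lambda: [
            features.build_feature_table(s, p, ev, config.window_s, config.step_s)
            for (s, _), p, ev in zip(cohort, cleaned, all_events)
        ],
    )
    table = pd.concat(tables, ignore_index=True)
    feat_path = out / "features.csv"
    table.to_csv(feat_path, index=False, float_format="%.9g")
    record("features", win_cfg, [feat_path])

    # 5. feature selection (reported globally; refitted per fold during CV)
    sel_seed = stage_seed(config.seed, "select")
    selections = run_stage(
        "select", {"seed": sel_seed},
        lambda: {
            scheme: features.lasso_select(
                table[features.FEATURE_NAMES],
                table["label2" if scheme == "two" else "label3"].to_numpy(),
                seed=sel_seed,
            )
            for scheme in config.class_schemes
        },
    )
    sel_path = out / "selection.json"
    sel_path.write_text(json.dumps(
        {
            scheme: {
                "selected": sel.selected,
                "alpha": sel.alpha,
                "dropped_constant": sel.dropped_constant,
            }
            for scheme, sel in selections.items()
        },
        indent=1, sort_keys=True,
    ))
    record("select", {"seed": sel_seed}, [sel_path])

    # 6. train final models on all windows (reference artifacts)
    train_seed = stage_seed(config.seed, "train")
    specs = [
        modeling.ModelSpec(classifier=c, class_scheme=s, random_seed=train_seed)
        for c in config.classifiers
        for s in config.class_schemes
    ]
    models = run_stage(
        "train", {"seed": train_seed, "specs": [f"{s.classifier}/{s.class_scheme}" for s in specs]},
        lambda: {
            (s.classifier, s.class_scheme): modeling.train(
                s, table, table[s.label_column].to_numpy(),
                selection=selections[s.class_scheme],
            )
            for s in specs
        },
    )
    models_path = out / "models.json"
    models_path.write_text(json.dumps(
        {
            f"{c}/{s}": {
                "hyperparameters": m.spec.resolved_hyperparameters(),
                "selected_features": m.selection.selected,
                "classes": m.classes,
            }
            for (c, s), m in models.items()
        },
        indent=1, sort_keys=True,
    ))
    record("train", {"seed": train_seed}, [models_path])

    # 7. evaluate
    eval_seed = stage_seed(config.seed, "evaluate")
    reports: dict[str, dict] = {}
    def do_eval():
        for spec in specs:
            for protocol in config.protocols:
                if protocol == "kfold10":
                    rep = evaluation.kfold10_evaluate(
                        table, spec, seed=eval_seed, tune=config.tune)
                elif protocol == "loso":
                    rep = evaluation.loso_evaluate(
                        table, spec, seed=eval_seed, tune=config.tune)
                else:
                    raise ValueError(f"unknown protocol {protocol!r}")
                key = f"{protocol}/{spec.class_scheme}/{spec.classifier}"
                reports[key] = summarize_report(rep)
        return reports
    run_stage("evaluate", {"seed": eval_seed, "protocols": config.protocols}, do_eval)
    report_path = out / "reports.json"
    report_path.write_text(json.dumps(reports, indent=1, sort_keys=True))
    record("evaluate", {"seed": eval_seed}, [report_path])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return reports, manifest


def summarize_report(rep: evaluation.EvaluationReport) -> dict:
    """JSON-serializable summary of an evaluation report."""
    return {
        "protocol": rep.protocol,
        "classifier": rep.model_spec.classifier,
        "class_scheme": rep.model_spec.class_scheme,
        "mean_metrics": _round_tree(rep.mean_metrics),
        "pooled_confusion": {
            "classes": rep.confusion.classes,
            "table": rep.confusion.table.tolist(),
        },
        "per_task_accuracy": _round_tree(rep.per_task or {}),
        "n_folds": len(rep.fold_metrics),
    }


def _round_tree(obj, digits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_tree(v, digits) for k, v in obj.items()}
    if isinstance(obj, float):
        return round(obj, digits)
    return obj
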