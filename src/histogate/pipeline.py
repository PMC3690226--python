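"""End-to-end pipeline: simulate → (segment) → features → train → evaluate.

Driven by a YAML config; every stage writes its outputs under a run
directory together with a run manifest (config hash, seeds, package
version), so a run is fully reproducible from its config. Stages are
skipped when their outputs already exist for the same config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import (
    CaseRecord,
    learn_thresholds,
    records_from_cohort,
    train_svm,
)
from .evaluation import METHODS, EvalConfig, random_split_evaluate
from .histogram import DEFAULT_TH, LuminanceHistogram, luminance_range
from .phantom import PhantomParams, default_seeds_for_case, generate_cohort, load_cohort, write_cohort
from .segmentation import segment_tumor

__all__ = ["run_pipeline", "validate_config", "save_model", "load_model", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "out_dir": "runs/demo",
    "cohort": {"n_lym": 8, "n_gbm": 8, "seed": 11, "params": {}},
    "segmentation": {"enabled": False, "tolerance": 2.5},
    "features": {"th": DEFAULT_TH},
    "train": {"use_adc": True, "kernel": "linear", "C": 1.0},
    "evaluate": {
        "methods": ["full_hybrid"],
        "k_values": [3, 5],
        "repetitions": 50,
        "seed": 5,
    },
}

_SCHEMA: dict[str, set[str]] = {
    "": {"out_dir", "cohort", "segmentation", "features", "train", "evaluate"},
    "cohort": {"n_lym", "n_gbm", "seed", "params"},
    "segmentation": {"enabled", "tolerance"},
    "features": {"th"},
    "train": {"use_adc", "kernel", "C"},
    "evaluate": {"methods", "k_values", "repetitions", "seed"},
}


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Merge with defaults and validate; raises listing every offending key."""
    problems: list[str] = []

    def check_keys(section: str, given: Mapping[str, Any]) -> None:
        allowed = _SCHEMA[section]
        for key in given:
            if key not in allowed:
                problems.append(f"unknown key {'.'.join(filter(None, [section, key]))!r}")

    check_keys("", config)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for section, value in config.items():
        if section not in _SCHEMA[""]:
            continue
        if section == "out_dir":
            merged["out_dir"] = str(value)
            continue
        if not isinstance(value, Mapping):
            problems.append(f"section {section!r} must be a mapping")
            continue
        check_keys(section, value)
        merged[section].update(value)

    if not problems:
        valid_params = set(PhantomParams.__dataclass_fields__)
        for key in merged["cohort"]["params"]:
            if key not in valid_params:
                problems.append(f"unknown key 'cohort.params.{key}'")
        for m in merged["evaluate"]["methods"]:
            if m not in METHODS:
                problems.append(f"unknown method {m!r} in evaluate.methods")
        n_per_class = min(merged["cohort"]["n_lym"], merged["cohort"]["n_gbm"])
        for k in merged["evaluate"]["k_values"]:
            if not 1 <= int(k) <= n_per_class - 1:
                problems.append(
                    f"evaluate.k_values entry {k} must be in [1, {n_per_class - 1}] "
                    f"for {n_per_class} cases per class"
                )
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))
    return merged


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def save_model(model_path: str | Path, thresholds, svm, th: float, train: list[CaseRecord]) -> None:
    """Serialize a trained hybrid model as JSON (thresholds + training data)."""
    payload = {
        "format": "histogate-model-v1",
        "th": th,
        "thresholds": {
            "th_range_lym_max": thresholds.th_range_lym_max,
            "th_range_gli_min": thresholds.th_range_gli_min,
            "th_adc_lym_max": thresholds.th_adc_lym_max,
            "th_adc_gli_min": thresholds.th_adc_gli_min,
            "adc_enabled": thresholds.adc_enabled,
            "range_enabled": thresholds.range_enabled,
            "geometry_case": thresholds.geometry_case,
        },
        "svm": {"kernel": svm.kernel, "C": svm.C, "gamma": svm.gamma},
        "train": [
            {
                "case_id": c.case_id,
                "label": c.label,
                "adc_value": c.adc_value,
                "n_voxels": c.histogram.n_voxels,
                "freqs": c.histogram.freqs.tolist(),
            }
            for c in train
        ],
    }
    with open(model_path, "w") as fh:
        json.dump(payload, fh)


def load_model(model_path: str | Path):
    """Rebuild a HybridModel from JSON; the SVM is refit deterministically."""
    from .classifier import HybridModel, ThresholdSet

    with open(model_path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "histogate-model-v1":
        raise ValueError(f"unrecognized model file format in {model_path}")
    th = payload["th"]
    train = [
        CaseRecord(
            case_id=c["case_id"],
            histogram=LuminanceHistogram(freqs=np.array(c["freqs"]), n_voxels=c["n_voxels"]),
            range_feature=luminance_range(
                LuminanceHistogram(freqs=np.array(c["freqs"]), n_voxels=c["n_voxels"]), th
            ),
            adc_value=c["adc_value"],
            label=c["label"],
        )
        for c in payload["train"]
    ]
    tdict = payload["thresholds"]
    thresholds = ThresholdSet(
        th_range_lym_max=tdict["th_range_lym_max"],
        th_range_gli_min=tdict["th_range_gli_min"],
        th_adc_lym_max=tdict["th_adc_lym_max"],
        th_adc_gli_min=tdict["th_adc_gli_min"],
        adc_enabled=tdict["adc_enabled"],
        range_enabled=tdict["range_enabled"],
    )
    svm = train_svm(train, kernel=payload["svm"]["kernel"], C=payload["svm"]["C"], gamma=payload["svm"]["gamma"])
    return HybridModel(thresholds=thresholds, svm=svm, th=th)


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path | None = None) -> Path:
    """Run the full pipeline from a config mapping or YAML path.

    Returns the run directory; key artifacts are ``manifest.csv`` (cohort),
    ``features.csv``, ``model.json`` and ``results.csv``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = validate_config(config)
    run_dir = Path(out_dir) if out_dir is not None else Path(cfg["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)

    manifest_file = run_dir / "run_manifest.json"
    prior_hash = None
    if manifest_file.exists():
        with open(manifest_file) as fh:
            prior_hash = json.load(fh).get("config_hash")
    resume = prior_hash == chash

    # simulate
    cohort_manifest = run_dir / "manifest.csv"
    params = PhantomParams(**cfg["cohort"]["params"])
    if not (resume and cohort_manifest.exists()):
        cohort = generate_cohort(
            cfg["cohort"]["n_lym"], cfg["cohort"]["n_gbm"], params, seed=cfg["cohort"]["seed"]
        )
        write_cohort(cohort, run_dir, params=params)
    else:
        cohort = load_cohort(cohort_manifest)

    # segment (optional) + features
    features_file = run_dir / "features.csv"
    masks = None
    if cfg["segmentation"]["enabled"]:
        masks = [
            segment_tumor(
                c.volume, default_seeds_for_case(c), tolerance=cfg["segmentation"]["tolerance"]
            )
            for c in cohort
        ]
    records = records_from_cohort(cohort, th=cfg["features"]["th"], masks=masks)
    pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "label": c.label,
                "adc_value": c.adc_value,
                "range_value": c.range_feature.range_value,
                "lo_bin": c.range_feature.lo_bin,
                "hi_bin": c.range_feature.hi_bin,
                "n_voxels": c.histogram.n_voxels,
            }
            for c in records
        ]
    ).to_csv(features_file, index=False)

    # train on the full cohort
    thresholds = learn_thresholds(records, use_adc=cfg["train"]["use_adc"])
    svm = train_svm(records, kernel=cfg["train"]["kernel"], C=cfg["train"]["C"])
    save_model(run_dir / "model.json", thresholds, svm, cfg["features"]["th"], records)

    # evaluate
    frames = []
    for method in cfg["evaluate"]["methods"]:
        eval_cfg = EvalConfig(
            k_values=cfg["evaluate"]["k_values"],
            repetitions=cfg["evaluate"]["repetitions"],
            method=method,
            th=cfg["features"]["th"],
            kernel=cfg["train"]["kernel"],
            C=cfg["train"]["C"],
            seed=cfg["evaluate"]["seed"],
        )
        frames.append(random_split_evaluate(records, eval_cfg))
    results = pd.concat(frames, ignore_index=True)
    results.to_csv(run_dir / "results.csv", index=False, float_format="%.6f")

    with open(manifest_file, "w") as fh:
        json.dump(
            {
                "config_hash": chash,
                "config": cfg,
                "phantom_params": asdict(params),
                "version": __version__,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return run_dir
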