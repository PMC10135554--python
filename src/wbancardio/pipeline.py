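"""End-to-end orchestration: generate -> transmit -> extract -> select -> tune -> evaluate.

A single YAML-able config drives every stage; one global seed deterministically
derives per-stage and per-fold seeds (counter-based via ``numpy``'s
``SeedSequence``), so a rerun with the same config reproduces every report
bit-exactly. Each cross-validation fold fits its own feature extractors,
feature mask and tuned classifier on the training fold only; the test fold
never touches any fitted component.

The classification chain per fold is an sklearn ``Pipeline``:
``DeepFeatureUnion`` (autoencoder + 1D-CNN) -> ``IDOXFeatureSelector`` ->
``IDOXTunedBiLSTM``.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from sklearn.pipeline import Pipeline

from . import data as data_mod
from . import metrics as metrics_mod
from . import wban as wban_mod
from .bilstm import IDOXTunedBiLSTM
from .features import ConvAutoencoder, Conv1DFeatures, DeepFeatureUnion
from .selection import IDOXFeatureSelector

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "data": {
        "csv": None,  # path to a user-supplied dataset; otherwise synthesized
        "n_records": 1000,
        "ranges": {k: list(v) for k, v in data_mod.DEFAULT_RANGES.items()},
        "rule": "any",
        "distribution": "uniform",
    },
    "wban": {
        "enabled": False,
        "drop_on_failure": False,
        "frame_size": 16,
        "channels": [
            {"id": 0, "noise_scale": 0.1, "a": 100, "success_prob": 1.0},
        ],
    },
    "features": {
        "ae": {"n_filters": 8, "kernel_size": 2, "bottleneck_dim": 8, "epochs": 300},
        "cnn": {"n_filters": 24, "kernel_size": 2, "d_out": 8, "epochs": 2500},
    },
    "selection": {"population_size": 5, "iterations": 5, "penalty": 0.01, "cv": 3},
    "predictor": {
        "population_size": 5,
        "iterations": 5,
        "h_range": [2, 255],
        "merge_mode": "concatenation",
        "epochs": 80,
        "tune_epochs": 10,
        "max_train": 512,
        "lr": 0.03,
        "batch_size": 128,
    },
    "evaluation": {"k": 5, "committee": 3},
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(source=None) -> dict:
    """Merge a YAML file path / dict over the defaults."""
    if source is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    return _deep_merge(DEFAULT_CONFIG, source)


def stage_seeds(global_seed: int, n: int = 16) -> list[int]:
    """Counter-based per-stage seeds derived from the global seed (< 2^31)."""
    state = np.random.SeedSequence(global_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def make_fold_pipeline(config: dict, seed: int) -> Pipeline:
    """The per-fold classification chain as an sklearn Pipeline."""
    fcfg, scfg, pcfg = config["features"], config["selection"], config["predictor"]
    return Pipeline(
        [
            (
                "features",
                DeepFeatureUnion(
                    ae=ConvAutoencoder(**fcfg["ae"], random_state=seed),
                    cnn=Conv1DFeatures(**fcfg["cnn"], random_state=seed + 1),
                ),
            ),
            (
                "select",
                IDOXFeatureSelector(
                    population_size=scfg["population_size"],
                    iterations=scfg["iterations"],
                    penalty=scfg["penalty"],
                    cv=scfg["cv"],
                    random_state=seed + 2,
                ),
            ),
            (
                "clf",
                IDOXTunedBiLSTM(
                    population_size=pcfg["population_size"],
                    iterations=pcfg["iterations"],
                    h_range=tuple(pcfg["h_range"]),
                    merge_mode=pcfg["merge_mode"],
                    epochs=pcfg["epochs"],
                    tune_epochs=pcfg["tune_epochs"],
                    max_train=pcfg["max_train"],
                    lr=pcfg["lr"],
                    batch_size=pcfg["batch_size"],
                    random_state=seed + 3,
                ),
            ),
        ]
    )


@dataclass
class PipelineResult:
    pooled_report: metrics_mod.MetricReport
    fold_reports: list
    pooled_cm: metrics_mod.ConfusionMatrix
    fold_artifacts: list
    outdir: Path | None
    manifest: dict


def _prepare_dataset(config: dict, seed: int):
    dcfg = config["data"]
    if dcfg.get("csv"):
        df = data_mod.read_csv(dcfg["csv"])
        if "label" not in df.columns:
            df["label"] = data_mod.label_frame(df, dcfg["rule"])
        return df
    spec = data_mod.DatasetSpec(
        n_records=dcfg["n_records"],
        ranges={k: tuple(v) for k, v in dcfg["ranges"].items()},
        seed=seed,
        rule=dcfg["rule"],
        distribution=dcfg["distribution"],
    )
    return data_mod.generate_dataset(spec)


def run_pipeline(config: dict | str | Path | None = None, outdir=None) -> PipelineResult:
    """Execute every stage in order and persist artifacts under ``outdir``.

    Stage order mirrors the monitoring architecture: cohort generation (or CSV
    load), optional transmission simulation, then per-fold deep feature
    extraction, wrapper selection, hidden-unit tuning, training and prediction,
    pooled into a single confusion matrix and metric report.
    """
    config = load_config(config) if not isinstance(config, dict) else _deep_merge(
        DEFAULT_CONFIG, config
    )
    seeds = stage_seeds(config["seed"])
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    try:
        df = _prepare_dataset(config, seeds[0])
    except Exception as exc:
        raise StageError(f"stage 'data' failed: {exc}") from exc
    timings["data"] = time.perf_counter() - t0
    if outdir is not None:
        data_mod.write_csv(df, outdir / "dataset.csv")

    if config["wban"]["enabled"]:
        t0 = time.perf_counter()
        try:
            channels = [wban_mod.Channel(**c) for c in config["wban"]["channels"]]
            df, events = wban_mod.simulate_transmission(
                df,
                channels=channels,
                frame_size=config["wban"]["frame_size"],
                drop_on_failure=config["wban"]["drop_on_failure"],
                seed=seeds[1],
            )
            df = df.reset_index(drop=True)
        except Exception as exc:
            raise StageError(f"stage 'wban' failed: {exc}") from exc
        timings["wban"] = time.perf_counter() - t0
        if outdir is not None:
            with open(outdir / "events.jsonl", "w") as fh:
                for ev in events:
                    fh.write(json.dumps(ev) + "\n")

    fold_artifacts: list[dict] = []
    fold_seeds = stage_seeds(seeds[2], n=4 * config["evaluation"]["k"])

    committee = max(1, int(config["evaluation"].get("committee", 1)))

    def runner(train_df, test_df):
        """One fold: fit the chain once, then train ``committee - 1`` extra
        classifiers at the tuned H that differ only in initialization seed,
        and average the positive-class probabilities. Features, mask and H
        are shared, so this reduces classifier initialization variance
        without changing the architecture."""
        from .bilstm import BiLSTMClassifier

        i = len(fold_artifacts)
        Xtr = np.ascontiguousarray(train_df[list(data_mod.ATTRIBUTES)].to_numpy(float))
        ytr = train_df["label"].to_numpy(int)
        Xte = np.ascontiguousarray(test_df[list(data_mod.ATTRIBUTES)].to_numpy(float))
        t0 = time.perf_counter()
        pipe = make_fold_pipeline(config, fold_seeds[4 * i])
        pipe.fit(Xtr, ytr)
        clf = pipe.named_steps["clf"]
        probs = [pipe.predict_proba(Xte)[:, 1]]
        if committee > 1:
            Str = pipe[:-1].transform(Xtr)
            Ste = pipe[:-1].transform(Xte)
            final = clf.model_
            for j in range(1, committee):
                member = BiLSTMClassifier(
                    **{
                        **final.get_params(),
                        "random_state": final.random_state + 7919 * j,
                    }
                ).fit(Str, ytr)
                probs.append(member.predict_proba(Ste)[:, 1])
        scores = np.mean(probs, axis=0)
        y_pred = (scores > 0.5).astype(int)
        fold_artifacts.append(
            {
                "fold": i,
                "mask": pipe.named_steps["select"].mask_.indices.tolist(),
                "best_H": int(clf.best_h_),
                "committee": committee,
                "tuning_best_accuracy": clf.tuning_.best_accuracy,
                "tuning_evaluated": clf.tuning_.evaluated,
                "seconds": round(time.perf_counter() - t0, 2),
            }
        )
        return y_pred

    t0 = time.perf_counter()
    fold_reports, pooled, pooled_cm = metrics_mod.kfold_evaluate(
        runner, df, k=config["evaluation"]["k"], seed=seeds[3]
    )
    timings["evaluate"] = time.perf_counter() - t0

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config["seed"],
        "stage_seeds": seeds[:4],
        "n_records": int(pooled_cm.n),
        "pooled_confusion": {
            "hb": pooled_cm.hb, "hc": pooled_cm.hc, "hd": pooled_cm.hd, "he": pooled_cm.he,
        },
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
    }
    if outdir is not None:
        reports = {f"fold{i}": r for i, r in enumerate(fold_reports)}
        reports["pooled"] = pooled
        metrics_mod.write_report(reports, outdir / "report")
        with open(outdir / "fold_artifacts.json", "w") as fh:
            json.dump(fold_artifacts, fh, indent=2)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config, fh)

    return PipelineResult(pooled, fold_reports, pooled_cm, fold_artifacts, outdir, manifest)
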