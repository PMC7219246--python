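"""Pipeline configuration and the end-to-end runner.

All defaults equal the method's published operating point: 0.01--0.1 Hz
band, [5, 20) s averaging window, fourth-quartile threshold (q=0.75),
3 symmetric pairs, k=10 folds of 20 trials.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import classifier, evaluation, mapping, preprocess
from .core import Recording, slice_trials

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    band_low: float = 0.01
    band_high: float = 0.1
    window: tuple[float, float] = (5.0, 20.0)
    quartile: float = 0.75
    n_pairs: int = 3
    pairs: list[tuple[int, int]] | None = None  # explicit pairs skip selection
    select_channels: bool = True
    trial_average: bool = True
    uncertain_policy: str = "error"
    kfold_k: int = 10
    kfold_subsample: int = 20
    run_kfold: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("band edges must satisfy 0 < low < high")
        if not 0 < self.quartile < 1:
            raise ValueError("quartile must be in (0, 1)")
        if self.n_pairs < 1 and not self.pairs:
            raise ValueError("need at least one symmetric pair")
        if self.uncertain_policy not in ("error", "drop"):
            raise ValueError("uncertain_policy must be 'error' or 'drop'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        return d


def load_config(path) -> PipelineConfig:
    """Read a YAML/key-value config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "window" in raw:
        raw["window"] = tuple(raw["window"])
    if "pairs" in raw and raw["pairs"] is not None:
        raw["pairs"] = [tuple(p) for p in raw["pairs"]]
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig, recording: Recording) -> dict:
    """Preprocess -> slice -> (select) -> classify -> evaluate.

    Returns a JSON-serializable report with the resolved config, the
    selected pairs, per-trial decisions, confusion counts, rates and the
    two-segment ROC.  Any stage failure is re-raised with the stage name.
    """
    config.validate()
    report: dict = {"config": config.to_dict()}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    filtered = stage(
        "preprocess",
        preprocess.bandpass_recording,
        recording,
        config.band_low,
        config.band_high,
    )
    trials = stage("slice", slice_trials, filtered)
    trials = stage(
        "baseline", lambda ts: [preprocess.baseline_correct(t) for t in ts], trials
    )
    report["n_trials"] = len(trials)

    if config.pairs is not None:
        pairs = [tuple(p) for p in config.pairs]
    elif config.select_channels:
        ranking = stage(
            "mapping",
            mapping.select_pairs,
            trials,
            recording.montage,
            q=config.quartile,
            top_m=config.n_pairs,
            window=config.window,
            trial_average=config.trial_average,
        )
        pairs = ranking.selected
        report["ranking"] = [
            {"pair": list(p), "score": s}
            for p, s in zip(ranking.pairs, ranking.scores)
        ]
    else:
        pairs = list(recording.montage.pairs[: config.n_pairs])
    report["pairs"] = [list(p) for p in pairs]

    decisions = stage(
        "classify", classifier.classify_session, trials, pairs, config.window
    )
    report["decisions"] = [
        {
            "trial_id": i,
            "true_hand": truth,
            "condition": trials[i].condition,
            "CR": dec.CR,
            "CL": dec.CL,
            "label": dec.label,
        }
        for i, (truth, dec) in enumerate(decisions)
    ]

    table = stage("confusion", evaluation.confusion, decisions, config.uncertain_policy)
    report["confusion"] = {
        "TP": table.TP, "FP": table.FP, "TN": table.TN, "FN": table.FN,
        "dropped_uncertain": table.dropped_uncertain,
    }
    report["accuracy_pct"] = table.accuracy
    summary = stage("rates", evaluation.rates, table)
    curve = evaluation.roc(summary)
    report["rates"] = {"TPF": summary.TPF, "TNF": summary.TNF, "FPF": summary.FPF}
    report["roc"] = {"vertices": [list(v) for v in curve.vertices], "auc": curve.auc}

    if config.run_kfold:
        kres = stage(
            "kfold",
            evaluation.kfold_evaluate,
            trials,
            recording.montage,
            k=config.kfold_k,
            subsample_size=config.kfold_subsample,
            seed=config.seed,
            q=config.quartile,
            top_m=config.n_pairs,
            window=config.window,
            uncertain_policy=config.uncertain_policy,
        )
        report["kfold"] = kres.summary()
        report["kfold"]["fold_rates"] = [
            {"TPF": r.TPF, "TNF": r.TNF} for r in kres.fold_rates
        ]
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
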