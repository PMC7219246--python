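"""Confusion statistics, two-segment ROC, and k-fold cross-validation.

Right-hand trials are the positive class.  Rates are surfaced on the
percent scale:

    TPF = TP / (TP + FN) * 100      (sensitivity)
    TNF = TN / (TN + FP) * 100      (specificity)
    FPF = 100 - TNF

A binary vote classifier yields a single operating point, so the ROC is
the two-segment polyline (0,0)-(FPF,TPF)-(100,100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TASK_WINDOW, Montage, Trial
from .classifier import Decision, classify_trial

__all__ = [
    "ConfusionTable",
    "RatesSummary",
    "RocCurve",
    "confusion",
    "rates",
    "false_positive_fraction",
    "roc",
    "kfold_evaluate",
    "KfoldResult",
]


@dataclass(frozen=True)
class ConfusionTable:
    TP: int
    FP: int
    TN: int
    FN: int
    dropped_uncertain: int = 0

    @property
    def n_right(self) -> int:
        return self.TP + self.FN

    @property
    def n_left(self) -> int:
        return self.TN + self.FP

    @property
    def accuracy(self) -> float:
        """Correct decisions / all decided trials, percent."""
        total = self.TP + self.FP + self.TN + self.FN
        if total == 0:
            raise ValueError("empty confusion table")
        return (self.TP + self.TN) / total * 100.0


@dataclass(frozen=True)
class RatesSummary:
    TPF: float
    TNF: float

    @property
    def FPF(self) -> float:
        return false_positive_fraction(self.TNF)


def false_positive_fraction(tnf: float) -> float:
    """FPF = 100 - TNF on the percent scale."""
    return 100.0 - tnf


def confusion(
    decisions: list[tuple[str, Decision]],
    uncertain_policy: str = "error",
) -> ConfusionTable:
    """Tally decisions against ground truth.

    Under ``policy="error"`` an uncertain decision counts against its true
    class: FN when the truth is right, FP when the truth is left.  Under
    ``policy="drop"`` uncertain trials are excluded from the table and
    reported in ``dropped_uncertain``.
    """
    if uncertain_policy not in ("error", "drop"):
        raise ValueError(f"unknown uncertain policy {uncertain_policy!r}")
    tp = fp = tn = fn = dropped = 0
    for truth, dec in decisions:
        if truth not in ("left", "right"):
            raise ValueError(f"unknown truth label {truth!r}")
        label = dec.label
        if label == "uncertain":
            if uncertain_policy == "drop":
                dropped += 1
            elif truth == "right":
                fn += 1
            else:
                fp += 1
        elif truth == "right":
            if label == "right":
                tp += 1
            else:
                fn += 1
        else:
            if label == "left":
                tn += 1
            else:
                fp += 1
    return ConfusionTable(TP=tp, FP=fp, TN=tn, FN=fn, dropped_uncertain=dropped)


def rates(table: ConfusionTable) -> RatesSummary:
    """Sensitivity/specificity percentages from a confusion table."""
    if table.n_right == 0 or table.n_left == 0:
        raise ValueError("rates undefined: a class has no trials")
    return RatesSummary(
        TPF=table.TP / table.n_right * 100.0,
        TNF=table.TN / table.n_left * 100.0,
    )


@dataclass(frozen=True)
class RocCurve:
    vertices: tuple[tuple[float, float], ...]
    auc: float


def roc(summary: RatesSummary) -> RocCurve:
    """Two-segment ROC polyline and its trapezoid area on the unit square."""
    fpf, tpf = summary.FPF, summary.TPF
    vertices = ((0.0, 0.0), (fpf, tpf), (100.0, 100.0))
    xs = np.array([0.0, fpf, 100.0]) / 100.0
    ys = np.array([0.0, tpf, 100.0]) / 100.0
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(vertices=vertices, auc=auc)


@dataclass
class KfoldResult:
    fold_rates: list[RatesSummary]
    fold_tables: list[ConfusionTable]
    fold_pairs: list[list[tuple[int, int]]]

    @property
    def mean_tpf(self) -> float:
        return float(np.mean([r.TPF for r in self.fold_rates]))

    @property
    def mean_tnf(self) -> float:
        return float(np.mean([r.TNF for r in self.fold_rates]))

    @property
    def sd_tpf(self) -> float:
        return float(np.std([r.TPF for r in self.fold_rates], ddof=1))

    @property
    def sd_tnf(self) -> float:
        return float(np.std([r.TNF for r in self.fold_rates], ddof=1))

    def summary(self) -> dict:
        return {
            "k": len(self.fold_rates),
            "TPF_mean": self.mean_tpf,
            "TPF_sd": self.sd_tpf,
            "TNF_mean": self.mean_tnf,
            "TNF_sd": self.sd_tnf,
            "FPF_mean": 100.0 - self.mean_tnf,
        }


def _trial_key(trial: Trial) -> tuple:
    """Deterministic content digest, independent of list position."""
    import hashlib

    h = hashlib.sha1()
    for key in sorted(trial.data):
        h.update(np.ascontiguousarray(trial.data[key]).tobytes())
    return (trial.hand, trial.condition, h.hexdigest())


def kfold_evaluate(
    trials: list[Trial],
    montage: Montage,
    k: int = 10,
    subsample_size: int = 20,
    seed: int = 0,
    q: float = 0.75,
    top_m: int = 3,
    window: tuple[float, float] = TASK_WINDOW,
    uncertain_policy: str = "error",
) -> KfoldResult:
    """k-fold cross-validation of the full selection + classification stack.

    Trials are canonically ordered and partitioned into ``k`` held-out
    subsamples of ``subsample_size`` trials, balanced left/right where
    possible.  The channel-selection stage (the only data-driven part of
    the pipeline — the vote classifier itself has no parameters) is fitted
    on the training portion of each fold, then the held-out trials are
    classified and scored.
    """
    from .mapping import select_pairs

    need = k * subsample_size
    if len(trials) < need:
        raise ValueError(
            f"k-fold needs at least {need} trials (k={k} x {subsample_size}), "
            f"got {len(trials)}"
        )
    rng = np.random.default_rng(seed)
    # canonical content-based sort so a permuted input yields identical folds
    order = sorted(range(len(trials)), key=lambda i: _trial_key(trials[i]))
    left_idx = [i for i in order if trials[i].hand == "left"]
    right_idx = [i for i in order if trials[i].hand == "right"]
    rng.shuffle(left_idx)
    rng.shuffle(right_idx)

    half = subsample_size // 2
    folds: list[list[int]] = []
    pool = left_idx[k * half :] + right_idx[k * half :]
    for f in range(k):
        fold = left_idx[f * half : (f + 1) * half]
        fold += right_idx[f * half : (f + 1) * half]
        short = subsample_size - len(fold)
        if short > 0:  # unbalanced input: fill from the remainder pool
            fold += pool[:short]
            pool = pool[short:]
        folds.append(fold)

    fold_rates, fold_tables, fold_pairs = [], [], []
    for fold in folds:
        test_set = set(fold)
        train = [trials[i] for i in range(len(trials)) if i not in test_set]
        test = [trials[i] for i in fold]
        ranking = select_pairs(train, montage, q=q, top_m=top_m, window=window)
        decisions = [
            (t.hand, classify_trial(t, ranking.selected, window)) for t in test
        ]
        table = confusion(decisions, uncertain_policy)
        fold_tables.append(table)
        fold_rates.append(rates(table))
        fold_pairs.append(ranking.selected)
    return KfoldResult(
        fold_rates=fold_rates, fold_tables=fold_tables, fold_pairs=fold_pairs
    )
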