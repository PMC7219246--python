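"""Hemispheric-lateralization decision tree for left/right classification.

For each selected symmetric pair the left-minus-right HbO and HbR signals
are averaged over the task window.  A pair votes "right" when the HbO
difference is positive and the HbR difference negative (contralateral
activation of the left hemisphere), and "left" in the mirrored case; the
counters CR and CL are compared three ways to produce the label.  The rule
is parameter-free and scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import HBO, HBR, TASK_WINDOW, Trial, window_slice

__all__ = [
    "PairDifference",
    "Decision",
    "pair_differences",
    "classify",
    "classify_trial",
    "classify_session",
]


@dataclass(frozen=True)
class PairDifference:
    """Window-averaged left-minus-right differences for one symmetric pair."""

    pair: tuple[int, int]
    hbo: float
    hbr: float


@dataclass(frozen=True)
class Decision:
    CR: int
    CL: int

    @property
    def label(self) -> str:
        if self.CR > self.CL:
            return "right"
        if self.CR < self.CL:
            return "left"
        return "uncertain"


def pair_differences(
    trial: Trial,
    pairs: list[tuple[int, int]],
    window: tuple[float, float] = TASK_WINDOW,
) -> list[PairDifference]:
    """Left-minus-right window averages for each (left, right) channel pair."""
    sl = window_slice(window, trial.fs)
    out = []
    for lch, rch in pairs:
        hbo = float(
            (trial.get(lch, HBO)[sl] - trial.get(rch, HBO)[sl]).mean()
        )
        hbr = float(
            (trial.get(lch, HBR)[sl] - trial.get(rch, HBR)[sl]).mean()
        )
        out.append(PairDifference(pair=(lch, rch), hbo=hbo, hbr=hbr))
    return out


def classify(diffs: list[PairDifference]) -> Decision:
    """Count lateralization votes and decide left/right/uncertain.

    Strict inequalities: a pair with an exactly zero average increments
    neither counter.
    """
    if not diffs:
        raise ValueError("at least one pair difference is required")
    cr = sum(1 for d in diffs if d.hbo > 0 and d.hbr < 0)
    cl = sum(1 for d in diffs if d.hbo < 0 and d.hbr > 0)
    return Decision(CR=cr, CL=cl)


def classify_trial(
    trial: Trial,
    pairs: list[tuple[int, int]],
    window: tuple[float, float] = TASK_WINDOW,
) -> Decision:
    return classify(pair_differences(trial, pairs, window))


def classify_session(
    trials: list[Trial],
    pairs: list[tuple[int, int]],
    window: tuple[float, float] = TASK_WINDOW,
) -> list[tuple[str, Decision]]:
    """Classify every trial; returns (true hand, decision) per trial in order."""
    return [(t.hand, classify_trial(t, pairs, window)) for t in trials]
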