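"""Hemodynamic difference matrices and informative-channel selection.

The mapping stage turns baseline-corrected trials into channel-pair
connectivity matrices:

1. average each channel's signal over the task window (default [5, 20) s);
2. form the antisymmetric matrix of pairwise channel differences;
3. keep positive entries for HbO (negative for HbR), take absolute values,
   and zero everything below the fourth quartile of the kept-value
   empirical CDF;
4. score symmetric channel pairs by their total connectivity strength and
   rank them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CHROMOPHORES, HBO, HBR, TASK_WINDOW, Montage, Trial, window_slice

__all__ = [
    "WindowAverages",
    "DifferenceMatrix",
    "ConnectivityMatrix",
    "ChannelRanking",
    "window_average",
    "difference_matrix",
    "quartile_filter",
    "rank_channels",
    "average_trials",
    "connectivity_from_trials",
    "select_pairs",
]


@dataclass
class WindowAverages:
    """Per (channel, chromophore) scalar mean over one time window."""

    values: dict[tuple[int, str], float]
    window: tuple[float, float]

    def get(self, channel: int, chromophore: str) -> float:
        return self.values[(channel, chromophore)]

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(sorted({ch for ch, _ in self.values}))


@dataclass
class DifferenceMatrix:
    """Antisymmetric matrix of pairwise window-average differences.

    ``matrix[a, b]`` is the average of channel ``channels[a]`` minus the
    average of channel ``channels[b]``.
    """

    chromophore: str
    channels: tuple[int, ...]
    matrix: np.ndarray

    def entry(self, ch_i: int, ch_j: int) -> float:
        i = self.channels.index(ch_i)
        j = self.channels.index(ch_j)
        return float(self.matrix[i, j])


@dataclass
class ConnectivityMatrix:
    """Sign-filtered, quartile-thresholded nonnegative connectivity matrix."""

    chromophore: str
    channels: tuple[int, ...]
    matrix: np.ndarray
    quartile: float = 0.75
    hand: str | None = None  # which hand's trials produced it, if known

    def entry(self, ch_i: int, ch_j: int) -> float:
        i = self.channels.index(ch_i)
        j = self.channels.index(ch_j)
        return float(self.matrix[i, j])

    def strength(self, channel: int) -> float:
        """Total connectivity involving ``channel`` (row + column sums)."""
        k = self.channels.index(channel)
        return float(self.matrix[k, :].sum() + self.matrix[:, k].sum())


@dataclass
class ChannelRanking:
    """Symmetric pairs ordered by descending informativeness score."""

    pairs: list[tuple[int, int]]
    scores: list[float]
    selected: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(b > a for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")


def window_average(
    trial: Trial, window: tuple[float, float] = TASK_WINDOW
) -> WindowAverages:
    """Time-mean of each channel/chromophore over the half-open window."""
    a, b = window
    if not (0.0 <= a < b <= 35.0):
        raise ValueError(f"window [{a}, {b}) must lie within [0, 35) s")
    sl = window_slice(window, trial.fs)
    if sl.stop <= sl.start:
        raise ValueError(f"window [{a}, {b}) covers no samples at fs={trial.fs}")
    values = {key: float(arr[sl].mean()) for key, arr in trial.data.items()}
    return WindowAverages(values=values, window=window)


def difference_matrix(avgs: WindowAverages, chromophore: str) -> DifferenceMatrix:
    """Antisymmetric N x N matrix of pairwise window-average differences."""
    channels = avgs.channels
    h = np.array([avgs.get(ch, chromophore) for ch in channels])
    matrix = h[:, None] - h[None, :]
    return DifferenceMatrix(chromophore=chromophore, channels=channels, matrix=matrix)


def _empirical_cdf_ranks(values: np.ndarray) -> np.ndarray:
    """F(v) = (# kept values <= v) / n for each v, computed by counting."""
    n = len(values)
    return np.array([(values <= v).sum() / n for v in values])


def quartile_filter(
    dh: DifferenceMatrix, chromophore: str | None = None, q: float = 0.75
) -> ConnectivityMatrix:
    """Sign-filter, take absolute values, and keep the top quartile.

    For HbO only positive differences are kept (cortical activation raises
    oxyhemoglobin); for HbR only negative ones.  Among the kept absolute
    values, entries whose empirical-CDF rank ``F(v) = rank(v)/n`` falls
    below ``q`` are zeroed; ties at the threshold all survive.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quartile threshold must be in (0, 1), got {q}")
    chromophore = chromophore or dh.chromophore
    if chromophore == HBO:
        keep = dh.matrix > 0
    elif chromophore == HBR:
        keep = dh.matrix < 0
    else:
        raise ValueError(f"unknown chromophore {chromophore!r}")

    out = np.zeros_like(dh.matrix)
    kept = np.abs(dh.matrix[keep])
    if kept.size == 0:
        import warnings

        warnings.warn(
            f"no entries survive the sign filter for {chromophore}", stacklevel=2
        )
        return ConnectivityMatrix(
            chromophore=chromophore, channels=dh.channels, matrix=out, quartile=q
        )
    cdf = _empirical_cdf_ranks(kept)
    survive = np.zeros_like(keep)
    survive[keep] = cdf >= q
    out[survive] = np.abs(dh.matrix[survive])
    return ConnectivityMatrix(
        chromophore=chromophore, channels=dh.channels, matrix=out, quartile=q
    )


def rank_channels(
    matrices: list[ConnectivityMatrix],
    montage: Montage,
    top_m: int = 3,
) -> ChannelRanking:
    """Rank symmetric pairs by total connectivity strength.

    Each matrix must carry the ``hand`` of the trials it came from.  For
    right-hand matrices the left channel of each pair is scored (activity is
    contralateral); for left-hand matrices the right channel.  The score of
    a pair is the sum of row + column strengths across all supplied
    matrices; ties are broken by ascending left-channel id.
    """
    if not montage.pair_map:
        raise ValueError("montage has no symmetric pair map")
    if any(m.hand not in ("left", "right") for m in matrices):
        raise ValueError("every connectivity matrix must be labeled with a hand")
    scores: dict[tuple[int, int], float] = {}
    for pair in montage.pairs:
        lch, rch = pair
        score = 0.0
        for m in matrices:
            score += m.strength(lch if m.hand == "right" else rch)
        scores[pair] = score
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0][0]))
    pairs = [p for p, _ in ordered]
    vals = [s for _, s in ordered]
    return ChannelRanking(pairs=pairs, scores=vals, selected=pairs[:top_m])


def save_matrix_text(cm: ConnectivityMatrix | DifferenceMatrix, path, sep="\t") -> None:
    """Write a matrix as delimited text with a channel-id header row/column."""
    with open(path, "w") as fh:
        fh.write(sep.join(["channel"] + [str(c) for c in cm.channels]) + "\n")
        for ch, row in zip(cm.channels, cm.matrix):
            fh.write(sep.join([str(ch)] + [f"{v:.10g}" for v in row]) + "\n")


def load_matrix_text(path, sep="\t") -> tuple[tuple[int, ...], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        channels = tuple(int(c) for c in header[1:])
        rows = [
            [float(v) for v in line.rstrip("\n").split(sep)[1:]] for line in fh
        ]
    return channels, np.array(rows)


def plot_matrix(cm: ConnectivityMatrix, path, title: str | None = None) -> None:
    """Render a connectivity matrix heatmap to an image file (requires
    matplotlib, imported lazily)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(cm.matrix, cmap="viridis", origin="lower")
    ax.set_xticks(range(len(cm.channels)), cm.channels, fontsize=6, rotation=90)
    ax.set_yticks(range(len(cm.channels)), cm.channels, fontsize=6)
    ax.set_xlabel("channel j")
    ax.set_ylabel("channel i")
    ax.set_title(title or f"{cm.chromophore} connectivity")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def average_trials(trials: list[Trial]) -> Trial:
    """Element-wise average of same-shape trials (all same hand/condition)."""
    if not trials:
        raise ValueError("no trials to average")
    first = trials[0]
    keys = set(first.data)
    if any(set(t.data) != keys for t in trials):
        raise ValueError("trials must share channels/chromophores")
    data = {
        key: np.mean([t.data[key] for t in trials], axis=0) for key in keys
    }
    return Trial(
        hand=first.hand, condition=first.condition, fs=first.fs, data=data
    )


def connectivity_from_trials(
    trials: list[Trial],
    q: float = 0.75,
    window: tuple[float, float] = TASK_WINDOW,
    trial_average: bool = True,
) -> list[ConnectivityMatrix]:
    """Per-hand, per-chromophore connectivity matrices from labeled trials.

    By default the 10 trials of each hand are averaged before the window
    averaging so the CDF is computed on trial-averaged responses — one
    matrix per (hand, chromophore), never pooled.
    """
    out: list[ConnectivityMatrix] = []
    for hand in ("left", "right"):
        group = [t for t in trials if t.hand == hand]
        if not group:
            continue
        sources = [average_trials(group)] if trial_average else group
        for chrom in CHROMOPHORES:
            agg = None
            for src in sources:
                avgs = window_average(src, window)
                cm = quartile_filter(difference_matrix(avgs, chrom), q=q)
                agg = cm.matrix if agg is None else agg + cm.matrix
            out.append(
                ConnectivityMatrix(
                    chromophore=chrom,
                    channels=tuple(sorted({ch for ch, _ in sources[0].data})),
                    matrix=agg,
                    quartile=q,
                    hand=hand,
                )
            )
    return out


def select_pairs(
    trials: list[Trial],
    montage: Montage,
    q: float = 0.75,
    top_m: int = 3,
    window: tuple[float, float] = TASK_WINDOW,
    trial_average: bool = True,
) -> ChannelRanking:
    """Full channel-selection stage: trials -> ranked symmetric pairs."""
    matrices = connectivity_from_trials(
        trials, q=q, window=window, trial_average=trial_average
    )
    if not matrices:
        raise ValueError("no labeled trials supplied")
    return rank_channels(matrices, montage, top_m=top_m)
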