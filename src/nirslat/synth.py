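"""Synthetic fNIRS session generator.

Produces labeled continuous recordings with the statistical structure the
classifier assumes: a double-gamma hemodynamic response lateralized to the
hemisphere contralateral to the moving hand, antiphase HbO/HbR, and
physiological noise made of Mayer-wave (~0.1 Hz), respiratory (~0.25 Hz)
and cardiac (~1 Hz) sinusoids plus white noise and a slow drift.  Imagery
trials get a weaker, delayed response.

Everything is a pure function of the parameter set and its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import stats

from .core import (
    DEFAULT_FS,
    HBO,
    HBR,
    TRIAL_DURATION_S,
    TRIAL_PRE_S,
    ChromophoreSeries,
    Event,
    EventLog,
    Montage,
    Recording,
    default_montage,
)

__all__ = [
    "HrfParams",
    "NoiseParams",
    "SynthParams",
    "hrf_kernel",
    "generate_session",
    "balanced_schedule",
    "generate_benchmark",
]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma hemodynamic response shape."""

    peak_delay: float = 6.0  # s
    undershoot_delay: float = 16.0  # s
    undershoot_ratio: float = 1.0 / 6.0
    dispersion: float = 1.0
    duration: float = 30.0  # kernel support, s

    def __post_init__(self) -> None:
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("gamma delays must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """Physiological + instrumental noise amplitudes (uM).

    The three oscillations (Mayer wave, respiration, heartbeat) are
    systemic: one phase per component per session, shared across channels,
    with a per-channel amplitude jitter.  White noise is independent per
    channel; its HbR component is scaled by ``hbr_noise_scale`` because
    deoxyhemoglobin fluctuations are correspondingly smaller in
    concentration units.
    """

    mayer_amp: float = 0.1
    mayer_freq: float = 0.1
    resp_amp: float = 0.1
    resp_freq: float = 0.25
    cardiac_amp: float = 0.1
    cardiac_freq: float = 1.0
    white_sigma: float = 0.1
    hbr_noise_scale: float = 1.0 / 3.0
    amp_jitter: float = 0.2  # relative per-channel jitter of oscillation amps
    drift_slope: float = 0.001  # uM/s, random sign per channel


@dataclass(frozen=True)
class SynthParams:
    fs: float = DEFAULT_FS
    trials_per_condition: int = 10
    hrf: HrfParams = field(default_factory=HrfParams)
    exec_amplitude: float = 1.0  # HbO peak, uM
    hbr_ratio: float = -1.0 / 3.0
    imagery_scale: float = 0.4
    imagery_onset_delay: float = 10.0  # s
    contralateral_gain: float = 1.0
    ipsilateral_gain: float = 0.3
    informative_left: tuple[int, ...] = (2, 7, 8)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0
    start_pad: float = 15.0  # s of background before the first command
    end_pad: float = 5.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0.0 < self.imagery_scale <= 1.0:
            raise ValueError("imagery_scale must be in (0, 1]")
        amps = (
            self.noise.mayer_amp,
            self.noise.resp_amp,
            self.noise.cardiac_amp,
            self.noise.white_sigma,
        )
        if any(a < 0 for a in amps):
            raise ValueError("noise amplitudes must be nonnegative")

    def with_snr(self, snr: float, condition: str) -> "SynthParams":
        """Set the white-noise sigma so that HbO peak / sigma = snr."""
        peak = self.exec_amplitude
        if condition == "imagery":
            peak *= self.imagery_scale
        return replace(self, noise=replace(self.noise, white_sigma=peak / snr))


def hrf_kernel(params: HrfParams = HrfParams(), fs: float = DEFAULT_FS) -> np.ndarray:
    """Unit-peak double-gamma response sampled at fs over [0, duration) s.

    The kernel peaks near ``peak_delay`` seconds and carries a small late
    undershoot; its positive lobe dominates, so the integral is positive.
    """
    t = np.arange(int(np.round(params.duration * fs))) / fs
    d = params.dispersion
    peak = stats.gamma.pdf(t, params.peak_delay / d, scale=d)
    under = stats.gamma.pdf(t, params.undershoot_delay / d, scale=d)
    kernel = peak - params.undershoot_ratio * under
    return kernel / kernel.max()


def balanced_schedule(
    trials_per_hand: int, seed: int | None = None
) -> list[str]:
    """A left/right command schedule, shuffled if a seed is given."""
    hands = ["left", "right"] * trials_per_hand
    if seed is not None:
        np.random.default_rng(seed).shuffle(hands)
    return hands


def generate_session(
    params: SynthParams,
    condition: str,
    hands: list[str] | None = None,
    montage: Montage | None = None,
) -> Recording:
    """Simulate one continuous session of the given condition.

    ``hands`` is the command schedule; by default an alternating schedule
    with ``trials_per_condition`` trials per hand.  Commands are spaced
    35 s apart so each trial occupies its own epoch.
    """
    if condition not in ("execution", "imagery"):
        raise ValueError(f"unknown condition {condition!r}")
    montage = montage or default_montage()
    if hands is None:
        hands = ["left", "right"] * params.trials_per_condition
    fs = params.fs
    duration = params.start_pad + len(hands) * TRIAL_DURATION_S + params.end_pad
    n = int(np.round(duration * fs))
    t = np.arange(n) / fs

    onsets = [params.start_pad + TRIAL_PRE_S + k * TRIAL_DURATION_S for k in range(len(hands))]
    if onsets and onsets[-1] + TRIAL_DURATION_S - TRIAL_PRE_S > duration:
        raise ValueError("schedule exceeds record length")

    rng = np.random.default_rng(params.seed)
    kernel = hrf_kernel(params.hrf, fs)

    amp = params.exec_amplitude
    delay = 0.0
    if condition == "imagery":
        amp *= params.imagery_scale
        # imagery_onset_delay is the observed latency of the HbO response
        # culmination relative to the command; the underlying activation
        # shift subtracts the hemodynamic rise time so the simulated
        # response peaks at that latency.
        delay = max(0.0, params.imagery_onset_delay - params.hrf.peak_delay)

    # clean signal per channel (HbO); HbR is the scaled antiphase copy
    signal_hbo = {ch: np.zeros(n) for ch in montage.channel_ids}
    for onset, hand in zip(onsets, hands):
        if hand == "right":
            contra = list(params.informative_left)
            ipsi = [montage.pair_map[c] for c in contra]
        else:
            ipsi = list(params.informative_left)
            contra = [montage.pair_map[c] for c in ipsi]
        start = int(np.round((onset + delay) * fs))
        stop = min(start + len(kernel), n)
        seg = kernel[: stop - start]
        for ch in contra:
            signal_hbo[ch][start:stop] += params.contralateral_gain * amp * seg
        for ch in ipsi:
            signal_hbo[ch][start:stop] += params.ipsilateral_gain * amp * seg

    nz = params.noise
    components = (
        (nz.mayer_amp, nz.mayer_freq),
        (nz.resp_amp, nz.resp_freq),
        (nz.cardiac_amp, nz.cardiac_freq),
    )
    # one systemic phase per oscillation per chromophore, shared by channels
    phases = {
        (chrom, f): rng.uniform(0, 2 * np.pi)
        for chrom in (HBO, HBR)
        for _, f in components
    }
    series: dict[tuple[int, str], ChromophoreSeries] = {}
    for ch in montage.channel_ids:
        for chrom in (HBO, HBR):
            scale = 1.0 if chrom == HBO else nz.hbr_noise_scale
            noise = np.zeros(n)
            for a, f in components:
                jitter = 1.0 + nz.amp_jitter * rng.uniform(-1, 1)
                noise += a * scale * jitter * np.sin(
                    2 * np.pi * f * t + phases[(chrom, f)]
                )
            noise += rng.normal(0.0, nz.white_sigma * scale, n)
            noise += rng.uniform(-1, 1) * nz.drift_slope * t
            clean = signal_hbo[ch] if chrom == HBO else params.hbr_ratio * signal_hbo[ch]
            series[(ch, chrom)] = ChromophoreSeries(
                channel_id=ch, chromophore=chrom, fs=fs, values=clean + noise
            )

    events = EventLog(
        [Event(onset=o, hand=h, condition=condition) for o, h in zip(onsets, hands)]
    )
    return Recording(montage=montage, series=series, events=events)


def generate_benchmark(
    white_sigmas: list[float],
    conditions: list[str] = ["execution", "imagery"],
    base_params: SynthParams = SynthParams(),
    seed: int = 0,
) -> tuple[list[Recording], dict]:
    """A reproducible grid of sessions plus a plain-text manifest.

    One recording per (sigma, condition); the manifest records every
    generator setting and the ground-truth schedule for each entry.
    """
    recordings: list[Recording] = []
    manifest: dict = {"base_seed": seed, "entries": []}
    k = 0
    for sigma in white_sigmas:
        for condition in conditions:
            p = replace(
                base_params,
                noise=replace(base_params.noise, white_sigma=sigma),
                seed=seed + k,
            )
            hands = balanced_schedule(p.trials_per_condition, seed=seed + k)
            rec = generate_session(p, condition, hands)
            recordings.append(rec)
            manifest["entries"].append(
                {
                    "index": k,
                    "condition": condition,
                    "white_sigma": sigma,
                    "seed": seed + k,
                    "hands": hands,
                    "onsets": [e.onset for e in rec.events],
                    # JSON-native form so the manifest round-trips losslessly
                    "params": json.loads(json.dumps(asdict(p))),
                }
            )
            k += 1
    return recordings, manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
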