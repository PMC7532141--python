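"""Seeded desk-scale generators with the statistical structure each pipeline
stage assumes: multi-scale class-coded waveforms for the classifier, spike
trains with planted R-peaks for the beat extractor, multi-electrode
oscillatory recordings for the montage/MFCC path, and irregular episode
tables with label-linked step changes for the EHR featurizer.

Every generator is a pure function of its spec: the same seed reproduces the
same dataset byte for byte.  These are statistical stand-ins, not
physiological simulations — no dynamical heart or brain model is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import EHR_FEATURE_CATALOG, TCP_ELECTRODES

__all__ = [
    "SynthSpec",
    "gen_multiscale",
    "gen_long_scale_pair",
    "gen_ecg_like",
    "gen_eeg_like",
    "gen_ehr_multilabel",
    "MULTISCALE_SHORT_PERIODS",
    "MULTISCALE_LONG_PERIODS",
]

TASKS = ("multiscale-multiclass", "ecg-beats", "eeg-like", "ehr-multilabel")

# Fixed per-class frequency tables (periods in samples).  Classes are laid out
# on a (short period, long period) grid, so telling all classes apart requires
# features at BOTH scales; every long period is >= 8x every short period.
MULTISCALE_SHORT_PERIODS = (12, 20)
MULTISCALE_LONG_PERIODS = (160, 240, 192, 320)


@dataclass(frozen=True)
class SynthSpec:
    """What to generate; ``n_classes`` doubles as the label count for the
    multi-label EHR task."""

    task: str = "multiscale-multiclass"
    n_samples: int = 400
    n_classes: int = 4
    sequence_length: int = 512
    noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.n_samples < self.n_classes:
            raise ValueError("n_samples must be >= n_classes")
        if min(self.n_samples, self.n_classes, self.sequence_length) < 1:
            raise ValueError("n_samples, n_classes, sequence_length must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _balanced_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.arange(n) % k
    return labels[rng.permutation(n)]


def multiscale_class_periods(c: int) -> tuple[int, int]:
    """(short, long) period of class ``c`` on the fixed frequency grid."""
    return (
        MULTISCALE_SHORT_PERIODS[c % len(MULTISCALE_SHORT_PERIODS)],
        MULTISCALE_LONG_PERIODS[c // len(MULTISCALE_SHORT_PERIODS)],
    )


def gen_multiscale(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Single-channel waveforms whose class is coded at two temporal scales.

    Each class is the sum of a short-period and a long-period unit sinusoid
    (random phases per sample) plus i.i.d. Gaussian noise; neighbouring
    classes share one of the two components, so no single scale separates
    all classes.  Returns ``(X [n, 1, T], labels [n])`` with balanced labels.
    """
    if spec.n_classes > 8:
        raise ValueError("gen_multiscale supports at most 8 classes")
    periods = [multiscale_class_periods(c) for c in range(spec.n_classes)]
    longest = max(p for pair in periods for p in pair)
    if spec.sequence_length < longest:
        raise ValueError(
            f"sequence_length {spec.sequence_length} shorter than the longest "
            f"class period {longest}"
        )
    rng = np.random.default_rng(spec.seed)
    labels = _balanced_labels(spec.n_samples, spec.n_classes, rng)
    t = np.arange(spec.sequence_length)
    x = np.empty((spec.n_samples, 1, spec.sequence_length))
    for i, c in enumerate(labels):
        ps, pl = periods[c]
        ph = rng.uniform(0, 2 * np.pi, size=2)
        wave = np.sin(2 * np.pi * t / ps + ph[0]) + np.sin(2 * np.pi * t / pl + ph[1])
        x[i, 0] = wave + rng.normal(0.0, spec.noise_sigma, spec.sequence_length)
    return x, labels


def gen_long_scale_pair(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two-class probe where the classes differ ONLY at the long scale.

    Both classes carry the same short-period component; the long-period
    component is the sole discriminant, so a model whose receptive field
    never spans a long period cannot separate them while a dilated stack can.
    """
    rng = np.random.default_rng(spec.seed)
    short = MULTISCALE_SHORT_PERIODS[0]
    longs = MULTISCALE_LONG_PERIODS[:2]  # 160 vs 240 samples
    if spec.sequence_length < max(longs):
        raise ValueError("sequence_length shorter than the longest class period")
    labels = _balanced_labels(spec.n_samples, 2, rng)
    t = np.arange(spec.sequence_length)
    x = np.empty((spec.n_samples, 1, spec.sequence_length))
    for i, c in enumerate(labels):
        ph = rng.uniform(0, 2 * np.pi, size=2)
        wave = np.sin(2 * np.pi * t / short + ph[0]) + np.sin(2 * np.pi * t / longs[c] + ph[1])
        x[i, 0] = wave + rng.normal(0.0, spec.noise_sigma, spec.sequence_length)
    return x, labels


def gen_ecg_like(
    spec: SynthSpec,
    sampling_rate: float = 125.0,
    bpm_per_class: Sequence[float] = (60.0, 90.0),
    width_s_per_class: Sequence[float] = (0.04, 0.08),
    interval_jitter: float = 0.05,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Single-lead signals with Gaussian-bump R-peaks at class-coded rates.

    Peaks are planted at jittered multiples of the class inter-beat interval
    (first peak half an interval in); amplitude-1 bumps of class-coded width
    ride on Gaussian noise.  Returns ``(signals [n, T], annotations, labels)``
    where ``annotations[i]`` is the planted peak sample indices of record i.
    ``interval_jitter`` is the s.d. of the interval perturbation as a
    fraction of the nominal interval; 0 gives exactly periodic peaks.
    """
    if spec.sequence_length < 10 * sampling_rate:
        raise ValueError("sequence_length must cover at least 10 s at the sampling rate")
    if spec.n_classes > len(bpm_per_class):
        raise ValueError("not enough per-class heart rates configured")
    rng = np.random.default_rng(spec.seed)
    labels = _balanced_labels(spec.n_samples, spec.n_classes, rng)
    t = np.arange(spec.sequence_length)
    signals = np.zeros((spec.n_samples, spec.sequence_length))
    annotations: list[np.ndarray] = []
    for i, c in enumerate(labels):
        interval = 60.0 / bpm_per_class[c] * sampling_rate
        width = width_s_per_class[c] * sampling_rate
        peaks = []
        pos = interval / 2.0
        while pos < spec.sequence_length:
            peaks.append(int(round(pos)))
            pos += interval * (1.0 + interval_jitter * rng.normal())
        peaks = np.array([p for p in peaks if 0 <= p < spec.sequence_length], dtype=int)
        sig = rng.normal(0.0, spec.noise_sigma, spec.sequence_length)
        for p in peaks:
            sig += np.exp(-0.5 * ((t - p) / width) ** 2)
        signals[i] = sig
        annotations.append(peaks)
    return signals, annotations, labels


def gen_eeg_like(
    spec: SynthSpec, sampling_rate: float = 250.0
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Multi-electrode recordings for the montage -> MFCC path.

    Each electrode carries an alpha-band (10 Hz) oscillation whose amplitude
    is modulated by the binary label (abnormal recordings show attenuated
    alpha with slow 2 Hz activity), plus electrode-specific Gaussian noise.
    Returns ``(recordings [n, E, T], electrode_names, labels [n])`` with the
    electrode set required by the standard bipolar montage.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(TCP_ELECTRODES)
    e = len(names)
    labels = _balanced_labels(spec.n_samples, 2, rng)
    t = np.arange(spec.sequence_length) / sampling_rate
    rec = np.empty((spec.n_samples, e, spec.sequence_length))
    for i, lab in enumerate(labels):
        alpha_amp = 1.0 if lab == 0 else 0.3
        slow_amp = 0.2 if lab == 0 else 1.0
        for j in range(e):
            ph = rng.uniform(0, 2 * np.pi, size=2)
            rec[i, j] = (
                alpha_amp * np.sin(2 * np.pi * 10.0 * t + ph[0])
                + slow_amp * np.sin(2 * np.pi * 2.0 * t + ph[1])
                + rng.normal(0.0, max(spec.noise_sigma, 1e-12), spec.sequence_length)
            )
    return rec, names, labels


def gen_ehr_multilabel(
    spec: SynthSpec,
    prevalences: Sequence[float] | None = None,
    effect_size: float = 1.0,
    features_per_label: int = 3,
    horizon_hours: float = 512.0,
    obs_rate_per_hour: float = 0.25,
    obs_noise: float = 0.3,
) -> tuple[list[pd.DataFrame], np.ndarray]:
    """Irregular episode tables with label-linked step changes.

    Each of ``n_classes`` (here: labels, at most 25) flips the mean of a
    disjoint block of ``features_per_label`` catalog features by
    ``effect_size`` from a random onset onwards.  Labels are independent
    Bernoulli draws with the given prevalences (default 0.3 each); every
    feature is observed at Poisson-process times (rate ``obs_rate_per_hour``)
    with Gaussian measurement noise.  Returns ``(episodes, labels [n, L])``
    where each episode is a (timestamp, feature, value) DataFrame with
    timestamps in hours from admission.
    """
    n_labels = spec.n_classes
    if n_labels > 25:
        raise ValueError("gen_ehr_multilabel supports at most 25 labels")
    if n_labels * features_per_label > len(EHR_FEATURE_CATALOG):
        raise ValueError("not enough catalog features for disjoint label blocks")
    if prevalences is None:
        prevalences = [0.3] * n_labels
    if len(prevalences) != n_labels:
        raise ValueError("prevalences length must equal the label count")
    rng = np.random.default_rng(spec.seed)
    labels = (rng.uniform(size=(spec.n_samples, n_labels)) < np.asarray(prevalences)).astype(int)
    episodes: list[pd.DataFrame] = []
    for i in range(spec.n_samples):
        onsets = rng.uniform(0.25 * horizon_hours, 0.75 * horizon_hours, size=n_labels)
        rows: list[tuple[float, str, float]] = []
        for fi, fname in enumerate(EHR_FEATURE_CATALOG):
            lab = fi // features_per_label if fi < n_labels * features_per_label else None
            n_obs = rng.poisson(obs_rate_per_hour * horizon_hours)
            times = np.sort(rng.uniform(0.0, horizon_hours, size=n_obs))
            if n_obs == 0:
                times = np.array([0.0])  # every episode observes every feature once
            for ts in times:
                val = rng.normal(0.0, obs_noise)
                if lab is not None and labels[i, lab] and ts >= onsets[lab]:
                    val += effect_size
                rows.append((float(ts), fname, float(val)))
        ep = pd.DataFrame(rows, columns=["timestamp", "feature", "value"])
        episodes.append(ep.sort_values("timestamp", kind="stable").reset_index(drop=True))
    return episodes, labels
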